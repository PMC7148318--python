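"""Signature assembly: random-forest importance filtering of DEGs.

The DEG list is reduced by impurity-based (Gini) variable importance from a
random forest classifying EGFR-mutant vs wild-type samples. Genes with zero
importance are dropped, the third quartile (linear-interpolation quantile) of
the remaining importances is computed, and genes strictly exceeding it are
kept. The survivors are partitioned into up/down sets by their DEG direction;
ALK is appended to the downregulated set because ALK-rearranged tumours are a
distinct, mutually exclusive driver class with suppressed EGFR dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .io import ExpressionMatrix, GeneSetCollection, _coerce_frame

__all__ = [
    "GeneSignature",
    "rf_importance",
    "select_by_importance",
    "assemble_signature",
    "derive_signature",
]

DEFAULT_APPEND_DOWN = ("ALK",)


@dataclass
class GeneSignature:
    """Paired up/down gene sets with the provenance of their derivation."""

    up_genes: list[str]
    down_genes: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.up_genes or not self.down_genes:
            raise ValueError("both up and down gene sets must be non-empty")
        if set(self.up_genes) & set(self.down_genes):
            overlap = sorted(set(self.up_genes) & set(self.down_genes))
            raise ValueError(f"up/down sets overlap: {overlap[:5]}")

    def to_collection(self) -> GeneSetCollection:
        return GeneSetCollection(
            sets={"EGFR_UP": list(self.up_genes), "EGFR_DOWN": list(self.down_genes)},
            descriptions={
                "EGFR_UP": "upregulated EGFR signature",
                "EGFR_DOWN": "downregulated EGFR signature",
            },
        )


def rf_importance(
    matrix: "ExpressionMatrix | pd.DataFrame",
    is_mutant: pd.Series,
    genes: Sequence[str],
    seed: int = 0,
    n_trees: int = 500,
    metric: str = "gini",
) -> pd.DataFrame:
    """Random-forest variable importance of ``genes`` for the mutant/wild-type
    classification. Impurity-based (Gini) by default; permutation importance is
    not offered because single-run permutation scores are too noisy for a
    quartile filter at these sample sizes. Reproducible given ``seed``."""
    if metric != "gini":
        raise ValueError(f"unsupported importance metric {metric!r}")
    df = _coerce_frame(matrix)
    missing = [g for g in genes if g not in df.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:5]}")
    labels = is_mutant.reindex(df.columns)
    if labels.isna().any():
        raise KeyError("every sample needs a group label")
    y = labels.astype(bool).to_numpy()
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("each class needs >=2 samples")
    X = df.loc[list(genes)].to_numpy().T  # samples x genes
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    forest.fit(X, y)
    return pd.DataFrame({"gene_id": list(genes), "importance": forest.feature_importances_})


def select_by_importance(records: pd.DataFrame) -> list[str]:
    """Drop zero-importance genes, then keep genes strictly above the third
    quartile of the remaining importances (linear-interpolation quantile).

    Output is ordered by decreasing importance (gene id breaks ties), so the
    selection is invariant to the ordering of the input records.
    """
    if len(records) == 0:
        raise ValueError("empty importance table")
    nonzero = records.loc[records["importance"] > 0]
    if len(nonzero) == 0:
        raise ValueError("no informative genes: all importances are zero")
    q3 = float(np.quantile(nonzero["importance"].to_numpy(), 0.75))
    selected = nonzero.loc[nonzero["importance"] > q3]
    if len(selected) == 0:
        raise ValueError(
            "empty selection: no importance strictly exceeds the third quartile "
            f"({q3:g})"
        )
    selected = selected.sort_values(
        ["importance", "gene_id"], ascending=[False, True], kind="stable"
    )
    return selected["gene_id"].tolist()


def assemble_signature(
    selected: Sequence[str],
    degs: pd.DataFrame,
    append_down: Sequence[str] = DEFAULT_APPEND_DOWN,
    provenance: dict | None = None,
) -> GeneSignature:
    """Partition selected genes by DEG direction and append ``append_down``
    genes (ALK by default) to the downregulated set, deduplicated."""
    direction = degs.set_index("gene_id")["direction"]
    missing = [g for g in selected if g not in direction.index]
    if missing:
        raise KeyError(f"selected genes missing from DEG table: {missing[:5]}")
    up = [g for g in selected if direction[g] == "up"]
    down = [g for g in selected if direction[g] == "down"]
    for gene in append_down:
        if gene not in down:
            down.append(gene)
    return GeneSignature(up_genes=up, down_genes=down, provenance=dict(provenance or {}))


def derive_signature(
    matrix: "ExpressionMatrix | pd.DataFrame",
    is_mutant: pd.Series,
    degs: pd.DataFrame,
    seed: int = 0,
    n_trees: int = 500,
    append_down: Sequence[str] = DEFAULT_APPEND_DOWN,
) -> GeneSignature:
    """DEG table -> importance filter -> assembled up/down signature."""
    genes = degs["gene_id"].tolist()
    imp = rf_importance(matrix, is_mutant, genes, seed=seed, n_trees=n_trees)
    selected = select_by_importance(imp)
    return assemble_signature(
        selected,
        degs,
        append_down=append_down,
        provenance={
            "seed": seed,
            "n_trees": n_trees,
            "n_degs": len(genes),
            "importance_metric": "gini",
            "quartile": "type-7 linear interpolation, strict >",
        },
    )
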