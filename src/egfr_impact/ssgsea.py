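"""Single-sample GSEA: rank-weighted random-walk enrichment scores.

For one sample, all N genes are ranked by expression within that sample
(ascending, so the most highly expressed gene has rank N; ties averaged).
Walking the genes in decreasing-rank order, two cumulative distributions are
tracked: the in-set distribution weighted by rank^alpha,

    P_in(i) = sum_{g in set, visited <= i} rank_g^alpha / sum_{g in set} rank_g^alpha,

and the uniform out-of-set distribution

    P_out(i) = #(out-of-set genes visited <= i) / (N - |set|).

The enrichment score is the sum of the differences over every position,
ES = sum_i [P_in(i) - P_out(i)] — the integrated deviation of the walk, not
its maximal excursion. Scores across a cohort are optionally divided by the
global (max - min) over all sets and samples, so a sample's normalized score
depends on the cohort it is scored with.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix, GeneSetCollection, _coerce_frame

__all__ = ["SsgseaParams", "SsgseaResult", "ssgsea_sample_score", "ssgsea"]


@dataclass
class SsgseaParams:
    """Rank-weighting exponent ``alpha`` (0 = unweighted walk) and whether to
    divide the score matrix by its global range. Ties are always averaged."""

    alpha: float = 0.25
    normalize: bool = True
    tie_method: str = "average"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.tie_method != "average":
            raise ValueError("only average tie handling is supported")


@dataclass
class SsgseaResult:
    """Enrichment scores, gene sets in rows, samples in columns."""

    scores: pd.DataFrame
    params: SsgseaParams
    raw_range: float | None = None


def ssgsea_sample_score(
    values: "pd.Series | np.ndarray",
    gene_ids: Sequence[str] | None,
    gene_set: Sequence[str],
    alpha: float = 0.25,
) -> float:
    """Unnormalized enrichment score of ``gene_set`` in one expression column.

    ``values`` may be a Series indexed by gene id (``gene_ids`` then optional)
    or an array paired with ``gene_ids``. Both the set intersection and its
    complement must be non-empty. Genes tied on rank are visited in gene-id
    order so the score does not depend on input row order.
    """
    if isinstance(values, pd.Series):
        gene_ids = values.index.to_numpy(dtype=object)
        expr = values.to_numpy(dtype=float)
    else:
        if gene_ids is None:
            raise ValueError("gene_ids required when values is a bare array")
        gene_ids = np.asarray(gene_ids, dtype=object)
        expr = np.asarray(values, dtype=float)
    n = expr.shape[0]
    in_set = np.isin(gene_ids, np.asarray(list(gene_set), dtype=object))
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("gene set has empty intersection with the matrix genes")
    if n_in == n:
        raise ValueError("gene set covers every gene; the out-of-set walk is undefined")

    ranks = rankdata(expr, method="average")  # ascending: top expression -> rank n
    # visit in decreasing rank; ties broken by gene id for order invariance
    order = np.lexsort((gene_ids, -ranks))
    in_sorted = in_set[order]
    weights = np.where(in_sorted, ranks[order] ** alpha, 0.0)
    p_in = np.cumsum(weights) / weights.sum()
    p_out = np.cumsum(~in_sorted) / (n - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea(
    matrix: "ExpressionMatrix | pd.DataFrame",
    sets: GeneSetCollection,
    params: SsgseaParams | None = None,
) -> SsgseaResult:
    """Score every gene set in every sample.

    Set members absent from the matrix are dropped with a warning. With
    ``params.normalize`` the whole score matrix is divided by its global
    max - min; a zero range is an error (degenerate cohort).
    """
    params = params or SsgseaParams()
    df = _coerce_frame(matrix)
    index = pd.Index(df.index)
    pruned: dict[str, list[str]] = {}
    for name, genes in sets.items():
        present = [g for g in genes if g in index]
        dropped = len(genes) - len(present)
        if dropped:
            warnings.warn(
                f"gene set {name!r}: {dropped} gene(s) absent from the matrix dropped",
                stacklevel=2,
            )
        if not present:
            raise ValueError(f"gene set {name!r} has no genes in the matrix")
        pruned[name] = present

    scores = pd.DataFrame(
        index=list(pruned), columns=df.columns, dtype=float
    )
    gene_ids = df.index.to_numpy(dtype=object)
    expr = df.to_numpy()
    for j, sample in enumerate(df.columns):
        col = expr[:, j]
        for name, genes in pruned.items():
            scores.at[name, sample] = ssgsea_sample_score(
                col, gene_ids, genes, alpha=params.alpha
            )

    raw_range = float(scores.to_numpy().max() - scores.to_numpy().min())
    if params.normalize:
        if raw_range == 0.0:
            raise ValueError("degenerate score range: all enrichment scores identical")
        scores = scores / raw_range
    return SsgseaResult(scores=scores, params=params, raw_range=raw_range)
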