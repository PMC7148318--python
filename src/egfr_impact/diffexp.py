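"""Differential expression between EGFR-mutant and wild-type samples.

The comparison uses a moderated t-statistic: per-gene pooled two-sample
variances are shrunk toward a common prior by empirical Bayes, with the prior
degrees of freedom ``d0`` and prior variance ``s0^2`` estimated by the
method-of-moments fit on the log sample variances (a scaled inverse
chi-square prior, the standard microarray moderation). KRAS-mutant samples
are excluded first, since KRAS sits downstream of EGFR signalling and would
confound the mutant/wild-type contrast. The DEG filter is
``p < 0.01 and fold change > 1.2 or < 1/1.2`` (strict inequalities), on raw
p-values; a Benjamini-Hochberg column is emitted for information only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ExpressionMatrix, _coerce_frame

__all__ = [
    "ModerationParameters",
    "exclude_kras_mutants",
    "estimate_moderation",
    "moderated_t_test",
    "filter_degs",
]

DEG_COLUMNS = [
    "gene_id",
    "mean_mut",
    "mean_wt",
    "log_fc",
    "fold_change",
    "t_stat",
    "p_value",
    "p_adj_bh",
    "direction",
]


@dataclass
class ModerationParameters:
    """Empirical-Bayes variance prior: ``d0`` prior df (may be inf), ``s0_sq``
    prior variance, ``per_gene_df`` residual df of each gene's pooled variance."""

    d0: float
    s0_sq: float
    per_gene_df: int

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError(f"d0 must be > 0, got {self.d0}")
        if not (self.s0_sq > 0):
            raise ValueError(f"s0_sq must be > 0, got {self.s0_sq}")


def exclude_kras_mutants(
    matrix: ExpressionMatrix, annotation: pd.DataFrame
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Drop KRAS-mutant samples from the cohort; sample order is preserved.

    Every matrix sample must have an annotation row (indexed by sample_id).
    """
    missing = [s for s in matrix.sample_ids if s not in annotation.index]
    if missing:
        raise KeyError(f"samples without annotation: {missing[:5]}")
    annot = annotation.loc[matrix.sample_ids]
    if "kras_status" in annot.columns:
        keep = annot["kras_status"].fillna("unknown") != "mutant"
    else:
        keep = pd.Series(True, index=annot.index)
    kept_ids = [s for s in matrix.sample_ids if keep[s]]
    if not kept_ids:
        raise ValueError("no samples remain after excluding KRAS mutants")
    return matrix.subset_samples(kept_ids), annot.loc[kept_ids]


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Monotone decreasing target; the iteration below converges for any y > 0.
    """
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif / x) < tol:
            break
    return x


def estimate_moderation(s2: np.ndarray, per_gene_df: int) -> ModerationParameters:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Matches the mean and variance of ``log(s_g^2)`` against their theoretical
    values under the prior, using digamma/trigamma moments of the log
    chi-square distribution. Genes with zero sample variance are excluded from
    the fit (their log variance is undefined) but still receive shrinkage.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        raise ValueError("need >=2 genes with positive variance to fit the prior")
    df = float(per_gene_df)
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        # no evidence of variance heterogeneity beyond sampling noise
        return ModerationParameters(d0=math.inf, s0_sq=math.exp(e_mean), per_gene_df=per_gene_df)
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return ModerationParameters(d0=d0, s0_sq=s0_sq, per_gene_df=per_gene_df)


def _posterior_variance(s2: np.ndarray, prior: ModerationParameters) -> np.ndarray:
    d0, dg = prior.d0, prior.per_gene_df
    if math.isinf(d0):
        return np.full_like(np.asarray(s2, dtype=float), prior.s0_sq)
    return (d0 * prior.s0_sq + dg * np.asarray(s2, dtype=float)) / (d0 + dg)


def moderated_t_test(
    matrix: "ExpressionMatrix | pd.DataFrame",
    is_mutant: pd.Series,
    moderation: bool = True,
    prior: ModerationParameters | None = None,
) -> pd.DataFrame:
    """Per-gene moderated t-test, mutant minus wild-type.

    Parameters
    ----------
    matrix
        Log2-scale genes x samples expression.
    is_mutant
        Boolean per-sample group labels indexed by sample id; must cover every
        sample and leave >=2 samples in each group.
    moderation
        When False, the ordinary pooled-variance two-sample t is computed
        (equivalent to d0 = 0).
    prior
        Optional fixed moderation parameters, bypassing estimation (e.g. the
        d0 -> inf limit where every gene shares the prior variance).

    Returns
    -------
    DataFrame with one row per gene: group means, ``log_fc`` (log2),
    ``fold_change`` (= 2**log_fc), moderated ``t_stat``, two-sided ``p_value``
    on d0 + (n1+n2-2) degrees of freedom, a BH-adjusted column, and the
    ``direction`` (up iff log_fc > 0).
    """
    df = _coerce_frame(matrix)
    labels = is_mutant.reindex(df.columns)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])[:5]
        raise KeyError(f"samples without group label: {missing}")
    labels = labels.astype(bool)
    mut = df.loc[:, labels.to_numpy()]
    wt = df.loc[:, (~labels).to_numpy()]
    n1, n2 = mut.shape[1], wt.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >=2 samples, got {n1} mutant / {n2} wild-type")

    mean_mut = mut.mean(axis=1).to_numpy()
    mean_wt = wt.mean(axis=1).to_numpy()
    log_fc = mean_mut - mean_wt
    dg = n1 + n2 - 2
    pooled_s2 = (mut.var(axis=1, ddof=1) * (n1 - 1) + wt.var(axis=1, ddof=1) * (n2 - 1)).to_numpy() / dg

    if prior is not None:
        mod = ModerationParameters(prior.d0, prior.s0_sq, dg)
        s2_post, df_total = _posterior_variance(pooled_s2, mod), mod.d0 + dg
    elif moderation:
        mod = estimate_moderation(pooled_s2, dg)
        s2_post, df_total = _posterior_variance(pooled_s2, mod), mod.d0 + dg
    else:
        mod = None
        s2_post, df_total = pooled_s2, float(dg)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(log_fc == 0.0, 0.0, log_fc / se)
    p_value = 2.0 * stats.t.sf(np.abs(t_stat), df=df_total)
    p_value = np.clip(p_value, np.finfo(float).tiny, 1.0)

    result = pd.DataFrame(
        {
            "gene_id": df.index,
            "mean_mut": mean_mut,
            "mean_wt": mean_wt,
            "log_fc": log_fc,
            "fold_change": np.exp2(log_fc),
            "t_stat": t_stat,
            "p_value": p_value,
            "p_adj_bh": stats.false_discovery_control(p_value, method="bh"),
            "direction": np.where(log_fc > 0, "up", "down"),
        }
    )
    result.attrs["moderation"] = mod
    return result


def filter_degs(
    records: pd.DataFrame, p_max: float = 0.01, fc_min: float = 1.2
) -> pd.DataFrame:
    """Retain genes with ``p_value < p_max`` and linear fold change strictly
    above ``fc_min`` or strictly below ``1/fc_min``."""
    if not (0 < p_max <= 1):
        raise ValueError(f"p_max must be in (0, 1], got {p_max}")
    if not (fc_min > 1):
        raise ValueError(f"fc_min must be > 1, got {fc_min}")
    fc = records["fold_change"]
    keep = (records["p_value"] < p_max) & ((fc > fc_min) | (fc < 1.0 / fc_min))
    return records.loc[keep].reset_index(drop=True)
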