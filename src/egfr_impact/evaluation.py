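"""Outcome evaluation of EI classes and impact scores.

Group comparisons use Welch's t (unequal variances, Satterthwaite df) — the
same operation serves impact-score contrasts, PD-L1 expression and mutation
burden. Associations with drug response (IC50, tumour shrinkage) use
Pearson's product-moment correlation. Survival endpoints (RFS/OS) are
compared by Kaplan-Meier curves with the two-group log-rank test, and by
multivariate Cox proportional-hazards regression (Efron tie handling, which
matters for months-resolution follow-up).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "SurvivalComparison",
    "CoxModel",
    "welch_t",
    "pearson_r",
    "km_logrank",
    "cox_multivariate",
]


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_stat: float
    df: float
    p_value: float


@dataclass
class CorrelationResult:
    n: int
    r: float
    p_value: float


@dataclass
class SurvivalComparison:
    endpoint: str
    groups: list[str]
    logrank_stat: float
    p_value: float
    km_curves: dict[str, pd.DataFrame]
    medians: dict[str, float] = field(default_factory=dict)


@dataclass
class CoxModel:
    covariates: list[str]
    hazard_ratios: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p_values: pd.Series
    loglik: float


def welch_t(
    values_a, values_b, group_a: str = "A", group_b: str = "B"
) -> GroupComparison:
    """Welch's two-sided t-test; each group needs >=2 finite values."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"each group needs >=2 values, got {a.size} and {b.size}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    res = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_stat=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue) if res.pvalue > 0 else np.finfo(float).tiny,
    )


def pearson_r(x, y) -> CorrelationResult:
    """Pearson correlation with the t-transform p-value on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"need n >= 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        n=int(x.size),
        r=float(res.statistic),
        p_value=float(res.pvalue) if res.pvalue > 0 else np.finfo(float).tiny,
    )


def km_logrank(times, events, groups, endpoint: str = "RFS") -> SurvivalComparison:
    """Kaplan-Meier curves per group and the two-group log-rank test.

    ``groups`` must take exactly two values; every comparison in this pipeline
    is two-group (or pairwise among curves). At least one event is required.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups, dtype=object)
    if not (times.size == events.size == groups.size):
        raise ValueError("times, events and groups must have equal length")
    if (times < 0).any():
        raise ValueError("negative survival times")
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    if events.sum() == 0:
        raise ValueError("no events observed in either group")
    for lab in labels:
        if (groups == lab).sum() == 0:  # unreachable given labels from data
            raise ValueError(f"group {lab!r} has zero subjects")

    curves: dict[str, pd.DataFrame] = {}
    medians: dict[str, float] = {}
    for lab in labels:
        mask = groups == lab
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], event_observed=events[mask], label=str(lab))
        table = kmf.event_table
        curves[str(lab)] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": table["at_risk"].reindex(
                    kmf.survival_function_.index, method="ffill"
                ).to_numpy(),
            }
        )
        medians[str(lab)] = float(kmf.median_survival_time_)

    mask_a = groups == labels[0]
    res = logrank_test(
        times[mask_a], times[~mask_a], events[mask_a], events[~mask_a]
    )
    return SurvivalComparison(
        endpoint=endpoint,
        groups=[str(l) for l in labels],
        logrank_stat=float(res.test_statistic),
        p_value=float(res.p_value) if res.p_value > 0 else np.finfo(float).tiny,
        km_curves=curves,
        medians=medians,
    )


def cox_multivariate(times, events, covariates: pd.DataFrame) -> CoxModel:
    """Cox proportional-hazards fit (Efron ties) with Wald CIs and p-values.

    Requires events >= number of covariates + 1 and a full-rank covariate
    matrix; collinear designs and non-convergence raise explicit errors.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    X = covariates.apply(pd.to_numeric)
    if len(X) != times.size:
        raise ValueError("covariate table length must match times")
    n_events = int(events.sum())
    if n_events < X.shape[1] + 1:
        raise ValueError(
            f"too few events ({n_events}) for {X.shape[1]} covariates"
        )
    centered = X.to_numpy() - X.to_numpy().mean(axis=0)
    if np.linalg.matrix_rank(centered) < X.shape[1]:
        raise ValueError("collinear covariates: design matrix is rank-deficient")

    frame = X.copy()
    frame["__time"] = times
    frame["__event"] = events.astype(int)
    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col="__time", event_col="__event")
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    summary = cph.summary
    return CoxModel(
        covariates=list(X.columns),
        hazard_ratios=summary["exp(coef)"],
        ci_lower=summary["exp(coef) lower 95%"],
        ci_upper=summary["exp(coef) upper 95%"],
        p_values=summary["p"],
        loglik=float(cph.log_likelihood_),
    )
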