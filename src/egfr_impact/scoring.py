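"""EGFR impact score, ROC threshold calibration, and EI-H/EI-L classification.

The impact score of a sample is

    (es_up + 1) / (es_down + 1)

where es_up / es_down are the sample's ssGSEA scores for the up- and
downregulated EGFR signatures. The EI-H/EI-L cutoff is calibrated by a full
ROC sweep against a binary truth (EGFR mutant vs wild-type in the derivation
cohort), choosing the threshold maximizing Youden's J = TPR - FPR; a
pre-calibrated cutoff (the published 2.2) can be supplied instead when
scoring external cohorts. Scores exactly at the threshold fall in EI-L.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection
from .signature import GeneSignature
from .ssgsea import SsgseaParams, ssgsea

__all__ = [
    "PUBLISHED_THRESHOLD",
    "ROCResult",
    "impact_score",
    "calibrate_threshold",
    "classify",
    "score_cohort",
]

#: EI-H/EI-L cutoff reported for the derivation cohort
PUBLISHED_THRESHOLD = 2.2

UP_SET = "EGFR_UP"
DOWN_SET = "EGFR_DOWN"


@dataclass
class ROCResult:
    """ROC sweep over candidate thresholds with the Youden-optimal choice."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    chosen_threshold: float
    youden_j: float


def impact_score(es_up, es_down):
    """(es_up + 1) / (es_down + 1); strictly increasing in es_up and strictly
    decreasing in es_down. Scalar or elementwise on arrays."""
    es_up = np.asarray(es_up, dtype=float)
    es_down = np.asarray(es_down, dtype=float)
    denom = es_down + 1.0
    if np.any(denom <= 0):
        raise ValueError(
            "denominator nonpositive: es_down + 1 <= 0 — normalized enrichment "
            "scores should not reach -1; check the score normalization"
        )
    out = (es_up + 1.0) / denom
    return float(out) if out.ndim == 0 else out


def calibrate_threshold(scores: Sequence[float], labels: Sequence[bool]) -> ROCResult:
    """Full ROC sweep and Youden-optimal cutoff.

    Candidate thresholds are the midpoints between consecutive distinct scores
    plus -inf/+inf sentinels; a sample is called positive when its score is
    strictly above the threshold. Ties on Youden's J break toward the smallest
    qualifying threshold. Both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both label classes must be present to calibrate")

    distinct = np.unique(scores)
    thresholds = np.concatenate(
        ([-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf])
    )
    # positive call: score > t
    tpr = np.array([(scores[labels] > t).mean() for t in thresholds])
    fpr = np.array([(scores[~labels] > t).mean() for t in thresholds])
    j = tpr - fpr
    best = int(np.argmax(j))  # argmax returns the first (smallest) qualifying t
    # AUC by trapezoid over the sweep (fpr decreases along increasing t)
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    return ROCResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        chosen_threshold=float(thresholds[best]),
        youden_j=float(j[best]),
    )


def classify(
    scores: pd.Series,
    threshold: float,
    provenance: dict | None = None,
) -> pd.DataFrame:
    """Assign EI_H (score strictly above threshold) or EI_L per sample."""
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    scores = pd.Series(scores, dtype=float)
    result = pd.DataFrame(
        {
            "sample_id": scores.index,
            "impact_score": scores.to_numpy(),
            "ei_class": np.where(scores.to_numpy() > threshold, "EI_H", "EI_L"),
            "threshold": threshold,
        }
    )
    result.attrs["provenance"] = dict(provenance or {})
    return result


def score_cohort(
    matrix: "ExpressionMatrix | pd.DataFrame",
    signature: "GeneSignature | GeneSetCollection",
    params: SsgseaParams | None = None,
    threshold: float | None = None,
) -> pd.DataFrame:
    """ssGSEA both signatures, form the impact score, optionally classify.

    Returns one row per sample: ``es_up``, ``es_down``, ``impact_score``, and
    when ``threshold`` is given also ``ei_class`` and ``threshold``.
    """
    params = params or SsgseaParams()
    if isinstance(signature, GeneSignature):
        collection = signature.to_collection()
    else:
        collection = signature
        if UP_SET not in collection.sets or DOWN_SET not in collection.sets:
            raise KeyError(f"gene set collection must contain {UP_SET!r} and {DOWN_SET!r}")
    es = ssgsea(matrix, collection, params)
    es_up = es.scores.loc[UP_SET]
    es_down = es.scores.loc[DOWN_SET]
    score = impact_score(es_up.to_numpy(), es_down.to_numpy())
    out = pd.DataFrame(
        {
            "sample_id": es.scores.columns,
            "es_up": es_up.to_numpy(),
            "es_down": es_down.to_numpy(),
            "impact_score": score,
        }
    )
    if threshold is not None:
        if not np.isfinite(threshold):
            raise ValueError(f"threshold must be finite, got {threshold}")
        out["ei_class"] = np.where(out["impact_score"] > threshold, "EI_H", "EI_L")
        out["threshold"] = threshold
    out.attrs["provenance"] = {
        "alpha": params.alpha,
        "normalize": params.normalize,
        "raw_range": es.raw_range,
        "n_up_genes": len(collection[UP_SET]),
        "n_down_genes": len(collection[DOWN_SET]),
    }
    return out
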