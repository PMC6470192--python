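"""Subject-level disease-warning classification from sCI trajectories.

Each subject's score series is reduced to one scalar (by default its peak —
a subject that ever enters the warning state carries a large sCI at some
time point), scores are compared between symptomatic (Sx) and asymptomatic
(Asx) subjects by ROC/AUC, and a single operating threshold is chosen by
Youden's J = tpr - fpr.  With cohorts of a dozen subjects every observed
score serves as a candidate threshold; no binning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .scoring import ScoreSeries

__all__ = [
    "ClassificationResult",
    "subject_score",
    "roc_auc",
    "choose_threshold",
    "predict",
]

POSITIVE = "Sx"
NEGATIVE = "Asx"


@dataclass
class ClassificationResult:
    """ROC/AUC evaluation of per-subject warning scores."""

    subject_ids: list[str]
    scores: np.ndarray
    labels: list[str]  # true labels, Sx/Asx
    roc: list[tuple[float, float]]  # (fpr, tpr), starts (0,0), ends (1,1)
    auc: float
    threshold: float | None = None
    predicted: list[str] = field(default_factory=list)
    accuracy: float | None = None


def subject_score(series: ScoreSeries, agg: str = "max", threshold: float | None = None) -> float:
    """Reduce a subject's sCI trajectory to a single warning score.

    ``max`` (default): the peak sCI.  ``mean``: the trajectory mean.
    ``earliest_above``: a time-to-threshold score — the negated rank of the
    first time point whose sCI exceeds ``threshold`` (earlier crossing =
    larger score; never crossing = -inf is avoided by returning minus the
    number of time points minus one).
    """
    if len(series) == 0:
        raise ValueError(f"subject {series.subject_id!r} has an empty score series")
    sci = series.sci
    if agg == "max":
        return float(sci.max())
    if agg == "mean":
        return float(sci.mean())
    if agg == "earliest_above":
        if threshold is None:
            raise ValueError("earliest_above aggregation requires a threshold")
        above = np.nonzero(sci > threshold)[0]
        if len(above) == 0:
            return float(-(len(sci) + 1))
        return float(-above[0])
    raise ValueError(f"unknown aggregation {agg!r}")


def roc_auc(scores: dict[str, float], labels: dict[str, str]) -> ClassificationResult:
    """ROC over all score thresholds and trapezoidal AUC.

    The AUC equals the Mann–Whitney statistic U / (n_Sx * n_Asx) with ties
    counted one half.  Requires both classes present.
    """
    subject_ids = sorted(scores)
    y_score = np.array([scores[s] for s in subject_ids], dtype=float)
    y_true = np.array([1 if labels[s] == POSITIVE else 0 for s in subject_ids])
    for s in subject_ids:
        if labels[s] not in (POSITIVE, NEGATIVE):
            raise ValueError(f"subject {s!r} has label {labels[s]!r}; need {POSITIVE}/{NEGATIVE}")
    if y_true.sum() == 0 or y_true.sum() == len(y_true):
        raise ValueError("both Sx and Asx subjects are required for ROC evaluation")

    fpr, tpr, _ = _roc_curve(y_true, y_score, drop_intermediate=False)
    roc = list(zip(fpr.tolist(), tpr.tolist()))
    area = float(_trapezoid_auc(fpr, tpr))
    return ClassificationResult(
        subject_ids=subject_ids,
        scores=y_score,
        labels=[labels[s] for s in subject_ids],
        roc=roc,
        auc=area,
    )


def choose_threshold(result: ClassificationResult, method: str = "youden",
                     fixed: float | None = None) -> float:
    """Pick the operating threshold on the warning score.

    ``youden``: candidate thresholds are the midpoints between consecutive
    distinct scores (plus one below the minimum and one above the maximum);
    the one maximising J = tpr - fpr wins, ties going to the highest
    threshold (the most specific operating point for a warning score).
    With perfect separation this returns the midpoint of the separating
    gap.  ``fixed`` passes the user's value through.
    """
    if method == "fixed":
        if fixed is None:
            raise ValueError("method='fixed' requires a threshold value")
        return float(fixed)
    if method != "youden":
        raise ValueError(f"unknown threshold method {method!r}")

    scores = result.scores
    y = np.array([1 if lab == POSITIVE else 0 for lab in result.labels])
    uniq = np.unique(scores)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    best_thr, best_j = None, -np.inf
    n_pos, n_neg = y.sum(), len(y) - y.sum()
    for thr in candidates:
        pred = scores > thr
        tprate = (pred & (y == 1)).sum() / n_pos
        fprate = (pred & (y == 0)).sum() / n_neg
        j = tprate - fprate
        if j >= best_j - 1e-15:  # ties keep the higher threshold
            best_j, best_thr = max(j, best_j), float(thr)
    return best_thr


def predict(
    scores: dict[str, float], threshold: float, labels: dict[str, str] | None = None
) -> tuple[dict[str, str], float | None]:
    """Label subjects by score > threshold -> Sx; accuracy if truth given."""
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    predicted = {s: (POSITIVE if v > threshold else NEGATIVE) for s, v in scores.items()}
    accuracy = None
    if labels is not None:
        known = [s for s in scores if labels.get(s) in (POSITIVE, NEGATIVE)]
        if known:
            accuracy = float(np.mean([predicted[s] == labels[s] for s in known]))
    return predicted, accuracy
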