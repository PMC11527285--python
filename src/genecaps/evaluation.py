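"""Classification metrics: confusion counts, ROC/AUROC, PR/AUPRC.

AUROC is computed from average ranks, which equals the Mann-Whitney
statistic P(score_pos > score_neg) + 0.5 P(tie) and the trapezoidal area
under the all-thresholds ROC curve.  AUPRC uses step-wise (non-linear)
interpolation of the precision-recall curve at every distinct score,
avoiding the optimistic bias of linear PR interpolation.  A sample is
predicted positive when its score is >= the threshold.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.stats


class MetricError(ValueError):
    """Metric undefined for this input (e.g. a single-class label vector)."""


def _check(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel()
    if scores.shape != labels.shape:
        raise MetricError(f"scores {scores.shape} vs labels {labels.shape}")
    if not np.all(np.isfinite(scores)):
        raise MetricError("scores contain NaN/Inf")
    if not np.all(np.isin(labels, (0, 1))):
        raise MetricError("labels must be binary 0/1")
    return scores, labels.astype(np.int64)


def confusion_at(scores, labels, threshold: float
                 ) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) at the given threshold (positive iff >=).

    TPR = TP / (TP + FN) and FPR = FP / (FP + TN) follow directly;
    both classes must be present for the rates to be defined.
    """
    scores, labels = _check(scores, labels)
    if labels.min() == labels.max():
        raise MetricError("confusion rates need both classes present")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return tp, fp, tn, fn


def auroc(scores, labels) -> float:
    """Rank-based AUROC with tie correction (ties count half)."""
    scores, labels = _check(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUROC needs both classes present")
    ranks = scipy.stats.rankdata(scores)  # average ranks
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def roc_points(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(thresholds desc, fpr, tpr) at every distinct score, with anchors."""
    scores, labels = _check(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise MetricError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    thresholds = np.r_[np.inf, s[distinct]]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    return thresholds, fpr, tpr


def pr_points(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(thresholds desc, recall, precision) at every distinct score."""
    scores, labels = _check(scores, labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise MetricError("PR curve needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    recall = tp / n_pos
    precision = tp / (tp + fp)
    return s[distinct], recall, precision


def auprc(scores, labels) -> float:
    """Area under precision-recall with step-wise interpolation.

    Area = sum over distinct thresholds of (R_i - R_{i-1}) * P_i, i.e.
    precision is held at its value on each recall step (average precision).
    """
    _, recall, precision = pr_points(scores, labels)
    r_prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - r_prev) * precision))


@dataclasses.dataclass
class EvalCurves:
    """ROC and PR curves plus their areas for one score/label vector."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    recall: np.ndarray
    precision: np.ndarray
    auroc: float
    auprc: float

    @classmethod
    def from_scores(cls, scores, labels) -> "EvalCurves":
        thr, fpr, tpr = roc_points(scores, labels)
        _, recall, precision = pr_points(scores, labels)
        return cls(thresholds=thr, fpr=fpr, tpr=tpr, recall=recall,
                   precision=precision, auroc=auroc(scores, labels),
                   auprc=auprc(scores, labels))
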