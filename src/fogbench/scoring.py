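"""The competition metric: per-sample average precision, averaged over classes.

Per-sample confidences are scored against expert video annotations with
non-interpolated (step) average precision, AP = sum_n (R_n - R_{n-1}) P_n
over descending unique score thresholds, ties grouped at one threshold.
The headline number is the unweighted mean of the three class APs (mAP),
with samples pooled across sessions per class (micro-averaging, matching a
single pooled submission).  Samples outside the Valid-and-Task mask are
dropped before any counting; "notype" FOG samples (class unknown) are
excluded from every per-class computation.

Metrics that are undefined for an input (no positives in the mask) raise
UndefinedMetricError instead of defaulting to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core_io import FOG_CLASSES, LabelSeries, ScoreSeries
from .errors import AlignmentError, UndefinedMetricError


def _masked(labels: np.ndarray, scores: np.ndarray,
            mask: Optional[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise AlignmentError("labels and scores length mismatch")
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != labels.shape:
            raise AlignmentError("mask length mismatch")
        labels, scores = labels[mask], scores[mask]
    return labels, scores


def _threshold_counts(labels: np.ndarray, scores: np.ndarray):
    """Cumulative TP/FP at each descending unique score threshold.

    Returns (thresholds, tp, fp) where tp[i]/fp[i] count positives/negatives
    with score >= thresholds[i]; tied scores collapse to one threshold.
    """
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order].astype(np.int64)
    # last index of each tie group
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tp = np.cumsum(y)[distinct]
    fp = (distinct + 1) - tp
    return s[distinct], tp, fp


def average_precision(labels: np.ndarray, scores: np.ndarray,
                      mask: Optional[np.ndarray] = None) -> float:
    """Non-interpolated AP of one class over masked samples."""
    y, s = _masked(labels, scores, mask)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise UndefinedMetricError("average precision undefined: no positive samples in mask")
    _, tp, fp = _threshold_counts(y, s)
    recall = tp / n_pos
    precision = tp / (tp + fp)
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def mean_average_precision(
    sessions: Sequence[tuple[LabelSeries, ScoreSeries, Optional[np.ndarray]]],
) -> dict:
    """mAP over a session set: pool samples per class, average the 3 class APs.

    Each element is (labels, scores, mask) for one session; ``mask`` may be
    None (defaults to the session's valid-and-task conjunction).  Returns
    {"per_class": {class: AP}, "mAP": float}.
    """
    per_class = {}
    for fog_class in FOG_CLASSES:
        pooled_y, pooled_s = [], []
        for labels, scores, mask in sessions:
            if mask is None:
                mask = labels.valid & labels.task
            keep = np.asarray(mask).astype(bool) & ~labels.notype
            pooled_y.append(labels.class_channel(fog_class)[keep])
            pooled_s.append(scores.class_channel(fog_class)[keep])
        y = np.concatenate(pooled_y) if pooled_y else np.array([], bool)
        s = np.concatenate(pooled_s) if pooled_s else np.array([], float)
        if y.sum() == 0:
            raise UndefinedMetricError(
                f"mAP undefined: class {fog_class!r} has no pooled positive samples")
        per_class[fog_class] = average_precision(y, s)
    return {"per_class": per_class,
            "mAP": float(np.mean(list(per_class.values())))}


@dataclass
class PRCurve:
    """Precision-recall curve: one point per unique threshold, high to low."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    fog_class: str = ""

    def __len__(self) -> int:
        return len(self.thresholds)


@dataclass
class ROCCurve:
    """ROC curve with trapezoidal AUC; points ordered by descending threshold."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    fog_class: str = ""


def pr_curve(labels: np.ndarray, scores: np.ndarray,
             mask: Optional[np.ndarray] = None, fog_class: str = "") -> PRCurve:
    y, s = _masked(labels, scores, mask)
    if y.sum() == 0:
        raise UndefinedMetricError("PR curve undefined: no positives in mask")
    thr, tp, fp = _threshold_counts(y, s)
    return PRCurve(thresholds=thr, precision=tp / (tp + fp),
                   recall=tp / y.sum(), fog_class=fog_class)


def roc_curve(labels: np.ndarray, scores: np.ndarray,
              mask: Optional[np.ndarray] = None, fog_class: str = "") -> ROCCurve:
    y, s = _masked(labels, scores, mask)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC undefined: needs >=1 positive and >=1 negative in mask")
    thr, tp, fp = _threshold_counts(y, s)
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=np.r_[np.inf, thr], fpr=fpr, tpr=tpr,
                    auc=auc, fog_class=fog_class)
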