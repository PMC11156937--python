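"""Operating-point selection and the threshold-metric family.

Score series are binarized at the threshold whose PR-curve point minimizes
the Euclidean distance to (1, 1) — perfect precision and recall.  At that
threshold we report F1, accuracy, precision, recall (sensitivity) and
specificity, per class and for the binary all-FOG case (any class or
notype vs. non-FOG).

Thresholds are selected per class independently, and separately for
all-FOG.  Distance ties break toward higher recall (a missed freeze costs
more clinically than a false alarm), then toward the lower threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core_io import FOG_CLASSES, LabelSeries, ScoreSeries
from .errors import AlignmentError
from .scoring import PRCurve, pr_curve

_TIE_RTOL = 1e-12


def select_threshold(curve: PRCurve) -> float:
    """Threshold of the PR point closest to (1,1); ties -> higher recall, then lower threshold."""
    if len(curve) == 0:
        raise ValueError("empty PR curve")
    d2 = (1.0 - curve.precision) ** 2 + (1.0 - curve.recall) ** 2
    best = d2.min()
    tied = np.flatnonzero(d2 <= best * (1 + _TIE_RTOL) + _TIE_RTOL)
    r = curve.recall[tied]
    tied = tied[r >= r.max() - _TIE_RTOL]
    return float(curve.thresholds[tied].min())


def binarize_all_fog(labels: LabelSeries, scores: ScoreSeries
                     ) -> tuple[np.ndarray, np.ndarray]:
    """All-FOG reduction: label = OR over classes and notype; score = max channel."""
    if len(labels) != len(scores):
        raise AlignmentError("labels and scores length mismatch")
    return labels.any_fog, scores.max_over_classes


@dataclass
class ConfusionMetrics:
    """Metrics of one masked 2x2 confusion table.

    ``precision`` (and consequently ``f1``) is None when there are no
    positive decisions; such undefined entries are excluded from aggregates
    rather than coerced to 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    threshold: Optional[float] = None

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / max(self.tp + self.fp + self.fn + self.tn, 1)

    @property
    def precision(self) -> Optional[float]:
        denom = self.tp + self.fp
        return self.tp / denom if denom else None

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else 0.0

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else 1.0

    @property
    def f1(self) -> Optional[float]:
        p = self.precision
        if p is None or (p + self.recall) == 0:
            return None
        return 2 * p * self.recall / (p + self.recall)

    def as_dict(self) -> dict:
        return {"threshold": self.threshold, "f1": self.f1,
                "accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "specificity": self.specificity,
                "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


def confusion_metrics(labels: np.ndarray, decisions: np.ndarray,
                      mask: Optional[np.ndarray] = None,
                      threshold: Optional[float] = None) -> ConfusionMetrics:
    labels = np.asarray(labels).astype(bool)
    decisions = np.asarray(decisions).astype(bool)
    if labels.shape != decisions.shape:
        raise AlignmentError("labels and decisions length mismatch")
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != labels.shape:
            raise AlignmentError("mask length mismatch")
        labels, decisions = labels[mask], decisions[mask]
    tp = int(np.sum(labels & decisions))
    fp = int(np.sum(~labels & decisions))
    fn = int(np.sum(labels & ~decisions))
    tn = int(np.sum(~labels & ~decisions))
    return ConfusionMetrics(tp=tp, fp=fp, fn=fn, tn=tn, threshold=threshold)


def operating_point_table(labels: LabelSeries, scores: ScoreSeries,
                          mask: Optional[np.ndarray] = None) -> dict[str, ConfusionMetrics]:
    """Per-class and all-FOG metrics at each channel's own PR-optimal threshold.

    Per-class rows exclude notype samples (class unknown); the all-FOG row
    includes them as positives.  A class with no masked positives has no
    defined operating point and is omitted from the table.
    """
    if mask is None:
        mask = labels.valid & labels.task
    mask = np.asarray(mask).astype(bool)
    out: dict[str, ConfusionMetrics] = {}
    for fog_class in FOG_CLASSES:
        class_mask = mask & ~labels.notype
        y = labels.class_channel(fog_class)
        s = scores.class_channel(fog_class)
        if not (y & class_mask).any():
            continue
        thr = select_threshold(pr_curve(y, s, class_mask, fog_class=fog_class))
        out[fog_class] = confusion_metrics(y, s >= thr, class_mask, threshold=thr)
    y_all, s_all = binarize_all_fog(labels, scores)
    thr = select_threshold(pr_curve(y_all, s_all, mask, fog_class="all_fog"))
    out["all_fog"] = confusion_metrics(y_all, s_all >= thr, mask, threshold=thr)
    return out
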