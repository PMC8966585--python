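"""Segmentation and classification metrics from confusion counts.

All metrics derive from the TP/FP/FN/TN tally of a binary prediction against
its ground truth (positive = foreground pixel / nodule).  Segmentation is
scored by IOU = TP/(TP+FP+FN) and the false positive rate FP/(FP+TN);
classification by accuracy, sensitivity, specificity, precision and F1.
Specificity defaults to the standard TN/(TN+FP); the ``fp_specificity``
flag instead returns FP/(FP+TN), i.e. the false positive rate, for
compatibility with conventions that report that ratio under the same name.
A metric with a zero denominator raises ``UndefinedMetricError`` rather
than silently returning 0.  ``standard_error`` is the sample standard
deviation of per-run metric values (deviations from the mean, n-1 divisor).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import UndefinedMetricError


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN tallies of a binary prediction."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricReport:
    """Container for whichever metrics a stage computes; unset fields are None."""

    iou: Optional[float] = None
    fpr: Optional[float] = None
    accuracy: Optional[float] = None
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    precision: Optional[float] = None
    f1: Optional[float] = None
    standard_error: Optional[float] = None

    def to_dict(self) -> dict[str, float]:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Elementwise TP/FP/FN/TN tally; inputs are boolean arrays of equal shape."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    return ConfusionCounts(
        tp=int(np.count_nonzero(pred & truth)),
        fp=int(np.count_nonzero(pred & ~truth)),
        fn=int(np.count_nonzero(~pred & truth)),
        tn=int(np.count_nonzero(~pred & ~truth)),
    )


def iou(c: ConfusionCounts) -> float:
    """Intersection over union TP/(TP+FP+FN)."""
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        raise UndefinedMetricError("IOU undefined: prediction and truth are both empty")
    return c.tp / denom


def fpr(c: ConfusionCounts) -> float:
    """False positive rate FP/(FP+TN)."""
    denom = c.fp + c.tn
    if denom == 0:
        raise UndefinedMetricError("FPR undefined: no negative samples")
    return c.fp / denom


def segmentation_metrics(pred: np.ndarray, truth: np.ndarray) -> MetricReport:
    """IOU and FPR of a predicted mask against ground truth."""
    c = confusion(pred, truth)
    return MetricReport(iou=iou(c), fpr=fpr(c))


def classification_metrics(c: ConfusionCounts, fp_specificity: bool = False) -> MetricReport:
    """Accuracy, sensitivity, specificity, precision and F1 from confusion counts.

    With ``fp_specificity=True`` the specificity slot holds FP/(FP+TN)
    instead of the standard TN/(TN+FP).
    """
    if c.total == 0:
        raise UndefinedMetricError("no samples")
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive samples")
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative samples")
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: no positive predictions")
    accuracy = (c.tp + c.tn) / c.total
    sensitivity = c.tp / (c.tp + c.fn)
    specificity = (c.fp if fp_specificity else c.tn) / (c.tn + c.fp)
    precision = c.tp / (c.tp + c.fp)
    if precision + sensitivity == 0:
        raise UndefinedMetricError("F1 undefined: precision + sensitivity is zero")
    f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return MetricReport(accuracy=accuracy, sensitivity=sensitivity,
                        specificity=specificity, precision=precision, f1=f1)


def standard_error(values) -> float:
    """Sample standard deviation of per-run metric values (n-1 divisor)."""
    values = np.asarray(list(values), dtype=float)
    if values.size < 2:
        raise ValueError("standard_error needs at least two values")
    deviations = values - values.mean()
    return float(np.sqrt((deviations**2).sum() / (values.size - 1)))
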