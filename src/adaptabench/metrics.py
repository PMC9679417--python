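"""Confusion-count bookkeeping and the seven binary-classification metrics.

The audit compares locked and retrained classifiers with seven metrics:
AUC, accuracy, sensitivity, specificity, F1, the Matthews correlation
coefficient (MCC) and balanced accuracy (BA).  MCC is the primary metric of
the framework: it ranges over [-1, 1] with -1 perfect misclassification and
+1 perfect classification, and it is robust to the class imbalance typical
of hepatotoxicity datasets.

Given confusion counts TP, TN, FP, FN with n = TP+TN+FP+FN::

    accuracy    = (TP + TN) / n
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 TP / (2 TP + FP + FN)
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    BA          = (sensitivity + specificity) / 2

Any metric whose denominator is zero is reported as NaN — an explicit
undefined marker, never silently coerced to 0.  AUC is the rank-based
(Mann-Whitney) statistic with midrank tie handling, i.e. the probability
that a random positive outranks a random negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "scalar_metrics",
    "auc",
    "metric_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts of a 2x2 confusion table; always partition the sample."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    """The seven metrics plus the confusion counts they derive from.

    Undefined metrics (zero denominator, or AUC on a single-class truth)
    are carried as ``nan``.
    """

    counts: ConfusionCounts
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    mcc: float
    ba: float

    def as_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc, "accuracy": self.accuracy,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "f1": self.f1, "mcc": self.mcc, "ba": self.ba,
        }


def confusion_counts(truth, predicted) -> ConfusionCounts:
    """Count TP/TN/FP/FN for binary truth and predicted label vectors."""
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if truth.shape != predicted.shape:
        raise ValueError(
            f"length mismatch: truth has {truth.size}, predicted has {predicted.size}"
        )
    if truth.size < 1:
        raise ValueError("need at least one observation")
    tp = int(np.sum((truth == 1) & (predicted == 1)))
    tn = int(np.sum((truth == 0) & (predicted == 0)))
    fp = int(np.sum((truth == 0) & (predicted == 1)))
    fn = int(np.sum((truth == 1) & (predicted == 0)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den else math.nan


def scalar_metrics(c: ConfusionCounts) -> dict[str, float]:
    """The six thresholded metrics from a confusion table.

    Returns a dict with keys ``accuracy, sensitivity, specificity, f1, mcc,
    ba``; a zero denominator yields NaN for that metric only.
    """
    if c.total < 1:
        raise ValueError("empty confusion table")
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    # product computed in float; exact for the integer ranges in practice
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, denom)
    return {
        "accuracy": _ratio(tp + tn, c.total),
        "sensitivity": sens,
        "specificity": spec,
        "f1": _ratio(2 * tp, 2 * tp + fp + fn),
        "mcc": mcc,
        "ba": (sens + spec) / 2.0,  # NaN propagates if either is undefined
    }


def auc(truth, scores) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling.

    Returns NaN when the truth vector contains a single class.
    """
    truth = np.asarray(truth, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if truth.shape != scores.shape:
        raise ValueError("truth and scores must have equal length")
    if len(np.unique(truth)) < 2:
        return math.nan
    return float(roc_auc_score(truth, scores))


def metric_report(truth, predicted, scores) -> MetricReport:
    """Compose confusion counts, the six scalar metrics, and AUC."""
    c = confusion_counts(truth, predicted)
    s = scalar_metrics(c)
    return MetricReport(counts=c, auc=auc(truth, scores), **s)
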