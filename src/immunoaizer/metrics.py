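"""Pixel-level segmentation metrics and ROC/AUC for mutation detection.

Segmentation metrics are macro-averaged over classes from one-vs-rest
confusion counts: IoU = TP/(TP+FP+FN), Dice = 2TP/(2TP+FP+FN),
precision = TP/(TP+FP), recall = TP/(TP+FN). A class absent from both the
prediction and the truth is excluded from the macro average; a class
present in exactly one of the two scores 0 for that metric. "Accuracy" is
overall (micro) pixel accuracy.

AUC uses the tie-aware Mann-Whitney rank statistic (probability that a
random positive outranks a random negative, ties counting one half), not a
trapezoid over a binned curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve


@dataclass
class ConfusionCounts:
    """One-vs-rest pixel counts per class; arrays of length ``n_classes``."""

    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    n_classes: int

    @property
    def total_pixels(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.tn[0] + self.fn[0])

    def present(self) -> np.ndarray:
        """Classes occurring in the prediction or the truth."""
        return (self.tp + self.fp + self.fn) > 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        if other.n_classes != self.n_classes:
            raise ValueError("class count mismatch")
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
            self.n_classes,
        )


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    dice: float
    iou: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "dice": self.dice,
            "iou": self.iou,
        }


def compress_to_labels(s: np.ndarray) -> np.ndarray:
    """Per-pixel argmax of a probability map (channel last); ties -> lowest class."""
    return np.asarray(s).argmax(axis=-1)


def confusion_counts(pred: np.ndarray, truth: np.ndarray, n_classes: int) -> ConfusionCounts:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    total = pred.size
    joint = np.bincount(
        (truth.ravel() * n_classes + pred.ravel()).astype(np.int64),
        minlength=n_classes * n_classes,
    ).reshape(n_classes, n_classes)
    tp = np.diag(joint).astype(np.int64)
    fp = joint.sum(axis=0) - tp  # predicted c, truth other
    fn = joint.sum(axis=1) - tp  # truth c, predicted other
    tn = total - tp - fp - fn
    return ConfusionCounts(tp, fp, tn, fn, n_classes)


def _macro(numer: np.ndarray, denom: np.ndarray, counts: ConfusionCounts) -> float:
    present = counts.present()
    if not present.any():
        return float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        per_class = np.where(denom > 0, numer / np.maximum(denom, 1), 0.0)
    return float(per_class[present].mean())


def per_class_iou(counts: ConfusionCounts) -> np.ndarray:
    denom = counts.tp + counts.fp + counts.fn
    with np.errstate(invalid="ignore"):
        return np.where(denom > 0, counts.tp / np.maximum(denom, 1), np.nan)


def per_class_dice(counts: ConfusionCounts) -> np.ndarray:
    denom = 2 * counts.tp + counts.fp + counts.fn
    with np.errstate(invalid="ignore"):
        return np.where(denom > 0, 2 * counts.tp / np.maximum(denom, 1), np.nan)


def macro_iou(counts: ConfusionCounts) -> float:
    return _macro(counts.tp, counts.tp + counts.fp + counts.fn, counts)


def macro_dice(counts: ConfusionCounts) -> float:
    return _macro(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn, counts)


def macro_precision(counts: ConfusionCounts) -> float:
    return _macro(counts.tp, counts.tp + counts.fp, counts)


def macro_recall(counts: ConfusionCounts) -> float:
    return _macro(counts.tp, counts.tp + counts.fn, counts)


def pixel_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    return float((pred == truth).mean())


def report_from_counts(counts: ConfusionCounts) -> MetricsReport:
    acc = float(counts.tp.sum()) / counts.total_pixels
    return MetricsReport(
        accuracy=acc,
        precision=macro_precision(counts),
        recall=macro_recall(counts),
        dice=macro_dice(counts),
        iou=macro_iou(counts),
    )


def roc_auc(scores, labels):
    """ROC points and tie-aware rank-statistic AUC.

    Returns ``(points, auc)`` where ``points`` is an (n, 2) array of
    (false-positive rate, true-positive rate) pairs. Raises ``ValueError``
    when only one label polarity is present (AUC undefined).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D arrays")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need both positive and negative labels")
    ranks = rankdata(scores)  # mid-ranks give ties 0.5 credit
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr]), float(auc)
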