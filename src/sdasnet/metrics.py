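"""Segmentation metrics: pixel accuracy, IoU/mIoU, F1 and the
threshold-sweep summaries of per-image foreground IoU.

Masks are binary rasters with background 0 and foreground 255 (or any
two-valued {0, positive} coding); the foreground is the positive class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.FP + other.FP,
                               self.FN + other.FN, self.TN + other.TN)


@dataclass
class MetricsReport:
    PA: float
    per_class_iou: list
    mIoU: float
    F1: float
    mIoU50: float
    mIoU50_95: float


def _as_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    values = np.unique(mask)
    if not np.all(np.isin(values, (0, 1, 255))):
        raise ValueError(f"mask is not binary: values {values[:10]}")
    return mask > 0


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Per-pixel tally with the foreground as positive class."""
    pred = _as_binary(pred)
    gt = _as_binary(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    return ConfusionCounts(
        TP=int(np.sum(pred & gt)),
        FP=int(np.sum(pred & ~gt)),
        FN=int(np.sum(~pred & gt)),
        TN=int(np.sum(~pred & ~gt)),
    )


def pixel_accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / all pixels."""
    if c.total == 0:
        raise ValueError("pixel accuracy undefined for zero pixels")
    return (c.TP + c.TN) / c.total


def mean_iou(pred: np.ndarray, gt: np.ndarray, num_classes: int = 2):
    """Per-class intersection/union and their mean.

    Classes whose union is empty (absent from both masks) are excluded from
    the mean; if every class is excluded the result is undefined.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if num_classes == 2:
        pred = _as_binary(pred).astype(np.int64)
        gt = _as_binary(gt).astype(np.int64)
    if pred.max(initial=0) >= num_classes or gt.max(initial=0) >= num_classes:
        raise ValueError("labels exceed num_classes")
    per_class = []
    included = []
    for cls in range(num_classes):
        p = pred == cls
        g = gt == cls
        union = int(np.sum(p | g))
        inter = int(np.sum(p & g))
        iou = inter / union if union else float("nan")
        per_class.append(iou)
        if union:
            included.append(iou)
    if not included:
        raise ValueError("mIoU undefined: all classes have empty union")
    return per_class, float(np.mean(included))


def f1_score(c: ConfusionCounts) -> float:
    """Harmonic mean of foreground precision and recall: 2TP/(2TP+FP+FN)."""
    denom = 2 * c.TP + c.FP + c.FN
    if denom == 0:
        warnings.warn("F1 undefined (no positives anywhere); returning 0.0")
        return 0.0
    return 2 * c.TP / denom


DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


def miou_thresholded(per_image_ious, thresholds=DEFAULT_THRESHOLDS):
    """Fraction of images whose foreground IoU clears each threshold.

    Returns (value at t=0.50, mean over t in {0.50, 0.55, ..., 0.95}).
    """
    ious = np.asarray(list(per_image_ious), dtype=float)
    if ious.size == 0:
        raise ValueError("no per-image IoUs given")
    if np.any((ious < 0) | (ious > 1)):
        raise ValueError("IoUs must lie in [0, 1]")
    fractions = [float(np.mean(ious >= t)) for t in thresholds]
    return fractions[0], float(np.mean(fractions))


def evaluate_masks(preds, gts, num_classes: int = 2) -> MetricsReport:
    """Aggregate metrics over paired prediction/label masks.

    PA, mIoU and F1 pool the confusion counts over all pixels of all images;
    the threshold-sweep summaries use per-image foreground IoU.
    """
    preds = list(preds)
    gts = list(gts)
    if not preds or len(preds) != len(gts):
        raise ValueError("need equal, non-empty prediction and label lists")
    total = ConfusionCounts(0, 0, 0, 0)
    per_image_fg_iou = []
    for p, g in zip(preds, gts):
        c = confusion_counts(p, g)
        total = total + c
        fg_union = c.TP + c.FP + c.FN
        per_image_fg_iou.append(c.TP / fg_union if fg_union else 1.0)
    pooled_pred = np.concatenate([np.asarray(p).ravel() for p in preds])
    pooled_gt = np.concatenate([np.asarray(g).ravel() for g in gts])
    per_class, miou = mean_iou(pooled_pred, pooled_gt, num_classes)
    m50, m5095 = miou_thresholded(per_image_fg_iou)
    return MetricsReport(
        PA=pixel_accuracy(total),
        per_class_iou=per_class,
        mIoU=miou,
        F1=f1_score(total),
        mIoU50=m50,
        mIoU50_95=m5095,
    )
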