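"""Evaluation metrics: confusion counts, threshold metrics, Dice/IoU,
HD95, and ROC/PR curves.

Undefined metrics (zero denominators) are reported as ``None`` rather
than coerced to 0 or 1, so macro averages stay honest. Segmentation
counts are voxel-level per class and macro-averaged across C1–C7 with
unweighted means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from sklearn.metrics import (auc as _sk_auc, precision_recall_curve,
                             roc_curve)

from .ctio import N_LEVELS

__all__ = [
    "ConfusionCounts",
    "confusion",
    "classification_metrics",
    "dice_iou",
    "hd95",
    "roc_pr",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred, labels) -> ConfusionCounts:
    """2×2 counts from equal-length binary decision/label sequences."""
    pred = np.asarray(pred).astype(bool)
    labels = np.asarray(labels).astype(bool)
    if pred.shape != labels.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {labels.shape}")
    return ConfusionCounts(
        tp=int(np.sum(pred & labels)),
        fp=int(np.sum(pred & ~labels)),
        fn=int(np.sum(~pred & labels)),
        tn=int(np.sum(~pred & ~labels)),
    )


def _safe_div(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def classification_metrics(counts: ConfusionCounts) -> dict:
    """Accuracy, precision, recall (sensitivity), F1, specificity and the
    false-negative rate. Zero-denominator metrics are ``None``."""
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = None
    if precision is not None and recall is not None \
            and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": (tp + tn) / counts.total,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "specificity": _safe_div(tn, tn + fp),
        "fn_rate": _safe_div(fn, tp + fn),
    }


def dice_iou(pred, gt) -> dict:
    """Per-class voxel Dice and IoU plus macro averages over C1–C7.

    ``Dice = 2TP/(2TP+FP+FN)``; ``IoU = TP/(TP+FP+FN)``; classes absent
    from both volumes are excluded from the macro mean.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    per_class = {}
    dices, ious = [], []
    for c in range(1, N_LEVELS + 1):
        p = pred == c
        g = gt == c
        if not p.any() and not g.any():
            per_class[c] = {"dice": None, "iou": None}
            continue
        tp = int(np.sum(p & g))
        fp = int(np.sum(p & ~g))
        fn = int(np.sum(~p & g))
        dice = 2 * tp / (2 * tp + fp + fn)
        iou = tp / (tp + fp + fn)
        per_class[c] = {"dice": dice, "iou": iou}
        dices.append(dice)
        ious.append(iou)
    return {
        "per_class": per_class,
        "macro_dice": float(np.mean(dices)) if dices else None,
        "macro_iou": float(np.mean(ious)) if ious else None,
    }


def _surface_points(mask: np.ndarray, spacing) -> np.ndarray:
    """Centers (mm) of labeled voxels with >= 1 face-adjacent background
    neighbor."""
    struct = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask, structure=struct,
                                      border_value=0)
    surf = mask & ~interior
    return np.argwhere(surf) * np.asarray(spacing, dtype=np.float64)


def hd95(pred, gt, spacing) -> float | None:
    """95th percentile of pooled symmetric surface distances (mm).

    Surface voxels of each mask are matched to the nearest surface voxel
    of the other; the two directed distance sets are pooled before
    taking the percentile. ``None`` when either mask is empty.
    """
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if not pred.any() or not gt.any():
        return None
    sp = _surface_points(pred, spacing)
    sg = _surface_points(gt, spacing)
    d_pg = cKDTree(sg).query(sp)[0]
    d_gp = cKDTree(sp).query(sg)[0]
    return float(np.percentile(np.concatenate([d_pg, d_gp]), 95))


def roc_pr(probabilities, labels) -> dict:
    """ROC points + trapezoidal AUC, PR points + prevalence baseline.

    Equal scores are grouped at one cut-point. Requires both classes.
    """
    scores = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if scores.shape != y.shape:
        raise ValueError("length mismatch")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    fpr, tpr, roc_thr = roc_curve(y, scores)
    precision, recall, pr_thr = precision_recall_curve(y, scores)
    return {
        "fpr": fpr,
        "tpr": tpr,
        "roc_thresholds": roc_thr,
        "auc": float(_sk_auc(fpr, tpr)),
        "precision": precision,
        "recall": recall,
        "pr_thresholds": pr_thr,
        "prevalence": float(y.mean()),
    }
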