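"""Segmentation evaluation metrics.

Per-image confusion metrics (IoU, Dice, sensitivity, specificity,
accuracy, reported as percentages), pixel-level ROC/AUC, and per-image
averaging across a test set (the dominant convention in the polyp
segmentation literature; pooled-confusion aggregation is deliberately
not used).
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

THRESHOLD = 0.5


@dataclass
class MetricsReport:
    iou: float
    dsc: float
    se: float
    sp: float
    acc: float
    auc: float | None = None
    n_images: int = 1

    def to_dict(self) -> dict:
        return asdict(self)


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> tuple[int, int, int, int]:
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    if not np.all((gt == 0) | (gt == 1)):
        raise ValueError("ground truth must be binary")
    gt = gt.astype(bool)
    tp = int(np.sum(pred & gt))
    fp = int(np.sum(pred & ~gt))
    fn = int(np.sum(~pred & gt))
    tn = int(np.sum(~pred & ~gt))
    return tp, fp, fn, tn


def metrics_from_counts(tp: int, fp: int, fn: int, tn: int) -> MetricsReport:
    n = tp + fp + fn + tn

    def pct(num, den, empty=100.0):
        return 100.0 * num / den if den else empty

    # Empty ground truth and empty prediction: a perfect match by convention.
    iou = pct(tp, tp + fp + fn)
    dsc = pct(2 * tp, 2 * tp + fp + fn)
    se = pct(tp, tp + fn)
    sp = pct(tn, tn + fp)
    acc = pct(tp + tn, n, empty=float("nan"))
    return MetricsReport(iou=iou, dsc=dsc, se=se, sp=sp, acc=acc)


def confusion_metrics(pred: np.ndarray, gt: np.ndarray) -> MetricsReport:
    """IoU/DSC/SE/SP/ACC (in %) for one binary prediction against one mask."""
    return metrics_from_counts(*confusion_counts(pred, gt))


def roc_auc(probs, gt):
    """Pixel-level AUC: P(random positive pixel outranks a random negative).

    Accepts a single map or a sequence of maps (pooled). Raises if the
    ground truth contains a single class only.
    """
    scores = np.concatenate([np.asarray(p).ravel() for p in np.atleast_1d(probs)]) \
        if isinstance(probs, (list, tuple)) else np.asarray(probs).ravel()
    labels = np.concatenate([np.asarray(g).ravel() for g in np.atleast_1d(gt)]) \
        if isinstance(gt, (list, tuple)) else np.asarray(gt).ravel()
    if labels.min() == labels.max():
        raise ValueError("AUC undefined: ground truth contains a single class")
    return float(roc_auc_score(labels, scores))


def roc_points(probs, gt):
    """ROC curve points (fpr, tpr, thresholds) over pooled pixels."""
    scores = np.asarray(probs).ravel()
    labels = np.asarray(gt).ravel()
    fpr, tpr, thr = roc_curve(labels, scores)
    return fpr, tpr, thr


def write_roc_csv(probs, gt, path) -> None:
    """Dump pooled-pixel ROC curve points as CSV (fpr, tpr, threshold)."""
    fpr, tpr, thr = roc_points(probs, gt)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["fpr", "tpr", "threshold"])
        for f, t, th in zip(fpr, tpr, thr):
            wr.writerow([f"{f:.6f}", f"{t:.6f}", f"{th:.6g}"])


def evaluate_images(probs: list[np.ndarray], gts: list[np.ndarray],
                    threshold: float = THRESHOLD) -> tuple[list[MetricsReport], MetricsReport]:
    """Per-image metrics plus the per-image average; AUC pooled over pixels."""
    if len(probs) != len(gts):
        raise ValueError("probability maps and masks differ in count")
    per_image = [confusion_metrics(np.asarray(p) >= threshold, g)
                 for p, g in zip(probs, gts)]
    agg = MetricsReport(
        iou=float(np.mean([m.iou for m in per_image])),
        dsc=float(np.mean([m.dsc for m in per_image])),
        se=float(np.mean([m.se for m in per_image])),
        sp=float(np.mean([m.sp for m in per_image])),
        acc=float(np.mean([m.acc for m in per_image])),
        n_images=len(per_image),
    )
    pooled_labels = np.concatenate([np.asarray(g).ravel() for g in gts])
    if pooled_labels.min() != pooled_labels.max():
        agg.auc = roc_auc([np.asarray(p) for p in probs], [np.asarray(g) for g in gts])
    return per_image, agg


def write_report(per_image: list[MetricsReport], agg: MetricsReport,
                 csv_path, json_path=None, ids=None) -> None:
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    with open(csv_path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["id", "iou", "dsc", "se", "sp", "acc"])
        for i, m in enumerate(per_image):
            name = ids[i] if ids else str(i)
            wr.writerow([name, f"{m.iou:.4f}", f"{m.dsc:.4f}", f"{m.se:.4f}",
                         f"{m.sp:.4f}", f"{m.acc:.4f}"])
        wr.writerow(["mean", f"{agg.iou:.4f}", f"{agg.dsc:.4f}", f"{agg.se:.4f}",
                     f"{agg.sp:.4f}", f"{agg.acc:.4f}"])
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(agg.to_dict(), fh, indent=2)
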