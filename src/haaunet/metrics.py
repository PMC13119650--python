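"""Segmentation, classification and timing metrics.

Dice (DSC), IoU, 95th-percentile Hausdorff distance, the four standard
confusion-matrix rates, and inference-timing summaries.  Composite tumor
regions (WT / TC / ET) are evaluated through the nested views derived from
the 4-class label map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .losses import boundary_pixels
from .phantoms import composite_views

__all__ = ["ConfusionCounts", "TimingReport", "dice_score", "iou_score",
           "hd95", "mask_hd95", "classification_rates", "timing_report",
           "evaluate_regions"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def validate(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("empty confusion matrix")


@dataclass(frozen=True)
class TimingReport:
    mean_inference_time: float
    fps: float
    n: int


def _check_pair(a, b):
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return a, b


def dice_score(a: np.ndarray, b: np.ndarray) -> float:
    """DSC = 2|X n Y| / (|X| + |Y|); both-empty convention: 1.0."""
    a, b = _check_pair(a, b)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def iou_score(a: np.ndarray, b: np.ndarray) -> float:
    """IoU = |X n Y| / |X u Y|; both-empty convention: 1.0."""
    a, b = _check_pair(a, b)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def hd95(a_points: np.ndarray, b_points: np.ndarray,
         spacing: float = 1.0) -> float:
    """95th-percentile symmetric Hausdorff distance between point sets.

    Takes the maximum of the 95th percentiles of the two directed
    nearest-neighbour distance distributions, scaled by `spacing` (mm/pixel).
    """
    a = np.atleast_2d(np.asarray(a_points, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b_points, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise ValueError("point sets must be non-empty")
    d_ab = cKDTree(b).query(a)[0]
    d_ba = cKDTree(a).query(b)[0]
    return float(spacing * max(np.percentile(d_ab, 95),
                               np.percentile(d_ba, 95)))


def mask_hd95(a: np.ndarray, b: np.ndarray, spacing: float = 1.0) -> float:
    """HD95 between the boundary point sets of two binary masks."""
    a, b = _check_pair(a, b)
    pa = np.argwhere(boundary_pixels(a))
    pb = np.argwhere(boundary_pixels(b))
    return hd95(pa, pb, spacing)


def classification_rates(c: ConfusionCounts) -> dict:
    """Sensitivity, specificity, accuracy, precision.

    A rate with zero denominator is reported as nan (undefined), never 0.
    """
    c.validate()

    def ratio(num, den):
        return float(num) / den if den > 0 else float("nan")

    return {
        "sensitivity": ratio(c.tp, c.tp + c.fn),
        "specificity": ratio(c.tn, c.tn + c.fp),
        "accuracy": ratio(c.tp + c.tn, c.tp + c.tn + c.fp + c.fn),
        "precision": ratio(c.tp, c.tp + c.fp),
    }


def timing_report(per_sample_times: list) -> TimingReport:
    t = np.asarray(per_sample_times, dtype=np.float64)
    if t.size == 0:
        raise ValueError("need at least one timing sample")
    total = float(t.sum())
    return TimingReport(mean_inference_time=total / t.size,
                        fps=t.size / total, n=int(t.size))


def evaluate_regions(pred_labels: np.ndarray, gt_labels: np.ndarray,
                     spacing: float = 1.0) -> dict:
    """Per-region (WT / TC / ET) Dice, IoU and HD95 for one case.

    HD95 is nan when either region is empty (no boundary to compare).
    """
    out = {}
    pred_views = composite_views(np.asarray(pred_labels))
    gt_views = composite_views(np.asarray(gt_labels))
    for region in ("WT", "TC", "ET"):
        p, g = pred_views[region], gt_views[region]
        row = {"dice": dice_score(p, g), "iou": iou_score(p, g)}
        try:
            row["hd95"] = mask_hd95(p, g, spacing)
        except ValueError:
            row["hd95"] = float("nan")
        out[region] = row
    return out
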