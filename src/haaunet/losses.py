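"""Composite segmentation objective and attention regularization.

The training objective is

    L_total = w1 * L_Dice + w2 * L_CE + w3 * L_boundary,

with defaults (w1, w2, w3) = (0.5, 0.3, 0.2), plus an attention-smoothness
penalty  L_attn = lambda * sum_i ||A_i - U||_F^2  with U the constant 0.5
map (the midpoint of the sigmoid range) and lambda = 0.001.

The boundary term is defined on hard boundary point sets: the mean squared
Euclidean distance from each predicted-boundary pixel to its nearest
ground-truth-boundary pixel (found via a distance transform).  During
network training the graph uses a distance-transform surrogate for this
term (see the training module); the functions here compute the exact
quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import ndimage

__all__ = ["LossConfig", "dice_loss", "cross_entropy_loss", "boundary_loss",
           "total_loss", "attention_regularizer", "boundary_pixels"]

EPS = 1e-7


@dataclass(frozen=True)
class LossConfig:
    w1: float = 0.5       # Dice
    w2: float = 0.3       # cross-entropy
    w3: float = 0.2       # boundary
    lambda_attn: float = 0.001

    def validate(self) -> None:
        if min(self.w1, self.w2, self.w3) < 0 or self.lambda_attn < 0:
            raise ValueError("loss weights must be nonnegative")
        if abs(self.w1 + self.w2 + self.w3 - 1.0) > 1e-9:
            warnings.warn("loss weights do not sum to 1", stacklevel=2)


def dice_loss(pred: np.ndarray, gt: np.ndarray, eps: float = EPS) -> float:
    """Soft Dice loss 1 - (2|X n Y| + eps) / (|X| + |Y| + eps), in [0, 1].

    `pred` may be a soft mask in [0, 1]; with both masks empty the eps
    convention returns 0.
    """
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError("shape mismatch")
    if pred.min() < 0 or pred.max() > 1:
        raise ValueError("pred must lie in [0, 1]")
    inter = (pred * gt).sum()
    return float(1.0 - (2.0 * inter + eps) / (pred.sum() + gt.sum() + eps))


def multiclass_dice_loss(prob: np.ndarray, labels: np.ndarray,
                         n_classes: int, eps: float = EPS) -> float:
    """Macro-averaged soft Dice over the foreground classes 1..C-1."""
    vals = [dice_loss(prob[..., c], labels == c, eps)
            for c in range(1, n_classes)]
    return float(np.mean(vals))


def cross_entropy_loss(pred: np.ndarray, gt_onehot: np.ndarray,
                       eps: float = EPS) -> float:
    """Pixel-wise cross-entropy -(1/N) sum_i sum_c y log y_hat (clamped)."""
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt_onehot, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError("shape mismatch")
    n = pred.size // pred.shape[-1]
    return float(-(gt * np.log(np.clip(pred, eps, 1.0))).sum() / n)


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """4-connected inner boundary: foreground pixels with a background neighbour."""
    mask = np.asarray(mask, dtype=bool)
    er = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1))
    return mask & ~er


def boundary_loss(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """Mean squared distance from predicted-boundary to GT-boundary pixels.

    An empty predicted boundary is assigned the squared image diagonal
    (the maximum possible penalty).
    """
    pred_mask = np.asarray(pred_mask, dtype=bool)
    gt_mask = np.asarray(gt_mask, dtype=bool)
    if pred_mask.shape != gt_mask.shape:
        raise ValueError("shape mismatch")
    if not gt_mask.any():
        raise ValueError("ground-truth mask is empty")
    b_pred = boundary_pixels(pred_mask)
    b_gt = boundary_pixels(gt_mask)
    h, w = pred_mask.shape
    if not b_pred.any():
        return float(h ** 2 + w ** 2)
    dist = ndimage.distance_transform_edt(~b_gt)
    return float((dist[b_pred] ** 2).mean())


def total_loss(pred_prob: np.ndarray, labels: np.ndarray,
               cfg: LossConfig | None = None, n_classes: int | None = None
               ) -> tuple[float, dict]:
    """Weighted composite loss on a per-pixel class-probability map.

    Returns (total, components) where components holds the unweighted
    Dice / CE / boundary values for logging.
    """
    cfg = cfg or LossConfig()
    cfg.validate()
    pred_prob = np.asarray(pred_prob, dtype=np.float64)
    labels = np.asarray(labels)
    c = n_classes or pred_prob.shape[-1]

    l_dice = multiclass_dice_loss(pred_prob, labels, c)
    onehot = np.eye(c)[labels]
    l_ce = cross_entropy_loss(pred_prob, onehot)
    pred_lab = pred_prob.argmax(axis=-1)
    bd = []
    for cls in range(1, c):
        if (labels == cls).any():
            bd.append(boundary_loss(pred_lab == cls, labels == cls))
    l_bd = float(np.mean(bd)) if bd else 0.0

    total = cfg.w1 * l_dice + cfg.w2 * l_ce + cfg.w3 * l_bd
    return float(total), {"dice": l_dice, "ce": l_ce, "boundary": l_bd}


def attention_regularizer(maps: list, lam: float = 0.001) -> float:
    """lambda * sum_i ||A_i - 0.5||_F^2 over the collected attention maps."""
    total = 0.0
    for m in maps:
        m = np.asarray(m, dtype=np.float64)
        if m.size and (m.min() < 0 or m.max() > 1):
            raise ValueError("attention maps must lie in [0, 1]")
        total += ((m - 0.5) ** 2).sum()
    return float(lam * total)
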