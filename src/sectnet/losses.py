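"""Training losses for probability-mask segmentation.

All losses accept a predicted probability mask (a :class:`Tensor` or
array with values in [0, 1]) and a binary target array of the same
shape, and return a scalar :class:`Tensor` through which gradients flow.

The primary objective is the Dice loss

    L = 1 - 2 * sum(y * p) / (sum(y^2) + sum(p^2) + eps),

which optimizes region overlap directly and is robust to the extreme
foreground/background imbalance of tumor masks.  BCE, Tversky and a
distance-transform Hausdorff surrogate are provided for comparison;
they are selectable by name through :data:`LOSSES`.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from .autodiff import Tensor, as_tensor

__all__ = ["dice_loss", "bce_loss", "tversky_loss", "hausdorff_loss",
           "LOSSES", "make_loss"]

EPS = 1e-6


def _prepare(pred, target) -> tuple[Tensor, np.ndarray]:
    pred = as_tensor(pred)
    target = np.asarray(target, dtype=np.float32)
    if pred.shape != target.shape:
        raise ValueError(f"prediction shape {pred.shape} != target shape {target.shape}")
    return pred, target


def dice_loss(pred, target, eps: float = EPS) -> Tensor:
    """Soft Dice loss with squared-term denominator and smoothing eps."""
    pred, target = _prepare(pred, target)
    inter = (pred * target).sum()
    denom = (pred * pred).sum() + float((target * target).sum()) + eps
    return 1.0 - (inter * 2.0) / denom


def tversky_loss(pred, target, alpha: float = 0.7, beta: float = 0.3,
                 eps: float = EPS) -> Tensor:
    """Tversky loss; alpha weights false positives, beta false negatives.

    At alpha = beta = 0.5 it coincides with the Dice loss on binary
    predictions.
    """
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be nonnegative")
    pred, target = _prepare(pred, target)
    tp = (pred * target).sum()
    fp = (pred * (1.0 - target)).sum()
    fn = ((1.0 - pred) * target).sum()
    return 1.0 - tp / (tp + alpha * fp + beta * fn + eps)


def bce_loss(pred, target, eps: float = 1e-7) -> Tensor:
    """Mean pixelwise binary cross-entropy with probability clamping."""
    pred, target = _prepare(pred, target)
    p = pred.clip(eps, 1.0 - eps)
    ll = p.log() * target + (1.0 - p).log() * (1.0 - target)
    return -ll.mean()


def hausdorff_loss(pred, target, threshold: float = 0.5, alpha: float = 2.0) -> Tensor:
    """Boundary-focused surrogate loss weighted by distance transforms.

    The squared prediction error at each pixel is weighted by
    ``dt(target)^alpha + dt(pred > threshold)^alpha``, where ``dt`` is
    the Euclidean distance to the respective foreground region; errors
    far from both boundaries therefore dominate.  The weights are
    treated as constants; gradients flow through the squared error.
    Returns 0 when prediction and target agree (including when both are
    empty).
    """
    pred, target = _prepare(pred, target)
    pred_bin = pred.data >= threshold
    tgt_bin = target >= 0.5

    def dist_to(fg: np.ndarray) -> np.ndarray:
        # distance from each pixel to the foreground region, per image;
        # an empty region is "infinitely far": use the image diagonal
        out = np.zeros(fg.shape, dtype=np.float32)
        flat = fg.reshape(-1, *fg.shape[-2:])
        oflat = out.reshape(-1, *fg.shape[-2:])
        diag = math.hypot(*fg.shape[-2:])
        for i in range(flat.shape[0]):
            if flat[i].any():
                oflat[i] = ndimage.distance_transform_edt(~flat[i])
            else:
                oflat[i] = diag
        return out

    weight = dist_to(tgt_bin) ** alpha + dist_to(pred_bin) ** alpha
    err = pred - target
    return (err * err * weight).mean()


LOSSES = {
    "dice": dice_loss,
    "bce": bce_loss,
    "tversky": tversky_loss,
    "hausdorff": hausdorff_loss,
}


def make_loss(name: str):
    try:
        return LOSSES[name.lower()]
    except KeyError:
        raise ValueError(f"unknown loss {name!r}; available: {sorted(LOSSES)}") from None
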