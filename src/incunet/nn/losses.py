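"""Differentiable training losses (autodiff-tensor counterparts of the
evaluation metrics in :mod:`incunet.metrics`)."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["soft_dice_loss", "binary_cross_entropy"]


def soft_dice_loss(pred: Tensor, target: np.ndarray, smooth: float = 1.0) -> Tensor:
    """1 - soft Dice over the whole batch.

    ``pred`` holds sigmoid probabilities, ``target`` a binary mask of the
    same shape.  The smoothing constant keeps the loss finite (and its
    gradient informative) when both prediction and target are empty.
    """
    target = np.asarray(target, dtype=np.float64)
    intersection = (pred * target).sum()
    total = pred.sum() + float(target.sum())
    dice = (2.0 * intersection + smooth) / (total + smooth)
    return 1.0 - dice


def binary_cross_entropy(pred: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean BCE on probabilities, clipped away from {0,1} for stability."""
    target = np.asarray(target, dtype=np.float64).reshape(pred.shape)
    p = pred.clip(eps, 1.0 - eps)
    loss = -(target * p.log() + (1.0 - target) * (1.0 - p).log())
    return loss.mean()
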