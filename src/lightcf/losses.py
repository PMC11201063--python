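"""Compound BCE-Dice segmentation loss.

loss = BCE(P, G) + (1 - (2 * sum(G*P) + sigma) / (sum(G) + sum(P) + sigma))

The binary cross-entropy term is averaged per pixel by default so the
loss scale does not grow with resolution; ``bce_reduction="sum"`` gives
the literal summed form. Predictions are clamped to [eps, 1-eps] before
the logarithms; the Dice complement needs no clamping thanks to the
smoothing constant sigma.
"""
from __future__ import annotations

import numpy as np

from . import nn
from .nn import tensor as T

EPS = 1e-7


def _check_binary(g: np.ndarray) -> None:
    if not np.all((g == 0) | (g == 1)):
        raise ValueError("ground-truth mask must be strictly binary {0, 1}")


def dice_loss(pred, target, smooth: float = 1.0):
    """Smoothed Dice complement, 0 iff pred == target exactly."""
    p = nn.as_tensor(pred)
    g = nn.as_tensor(target)
    inter = (p * g).sum()
    return 1.0 - (2.0 * inter + smooth) * T.pow_(p.sum() + g.sum() + smooth, -1.0)


def bce_loss(pred, target, reduction: str = "mean"):
    p = T.clip(nn.as_tensor(pred), EPS, 1.0 - EPS)
    g = nn.as_tensor(target)
    ll = g * T.log(p) + (1.0 - g) * T.log(1.0 - p)
    if reduction == "mean":
        return -ll.mean()
    if reduction == "sum":
        return -ll.sum()
    raise ValueError(f"unknown reduction {reduction!r}")


def bce_dice_loss(pred, target, smooth: float = 1.0, bce_reduction: str = "mean"):
    """Compound loss on a probability map and a binary mask of equal shape."""
    p = nn.as_tensor(pred)
    g = nn.as_tensor(target)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs target {g.shape}")
    _check_binary(g.data)
    return bce_loss(p, g, bce_reduction) + dice_loss(p, g, smooth)
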