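"""Training losses: soft Dice (1 - D) and categorical cross-entropy."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["dice_loss", "categorical_crossentropy"]

_EPS = 1e-7


def dice_loss(pred: Tensor, target: Tensor, smooth: float = 1.0) -> Tensor:
    """1 - soft Dice, averaged over batch and channels.

    ``smooth`` is added to numerator and denominator so empty masks with
    empty predictions score a loss of 0 instead of 0/0.
    """
    axes = tuple(range(1, len(pred.shape) - 1))  # spatial dims
    inter = (pred * target).sum(axis=axes)
    sums = pred.sum(axis=axes) + target.sum(axis=axes)
    sm = Tensor(np.float32(smooth))
    dice = (2.0 * inter + sm) * _recip(sums + sm)
    return 1.0 - dice.mean()


def _recip(t: Tensor) -> Tensor:
    out = Tensor(1.0 / t.data)
    out._prev = (t,)

    def _bw(g):
        t._accum(-g / (t.data * t.data))
    out._backward = _bw
    return out


def categorical_crossentropy(probs: Tensor, onehot: Tensor) -> Tensor:
    """Mean negative log-likelihood of one-hot targets under ``probs``."""
    clipped = Tensor(np.clip(probs.data, _EPS, 1.0))
    clipped._prev = (probs,)

    def _bw(g):
        inside = (probs.data > _EPS) & (probs.data < 1.0)
        probs._accum(g * inside)
    clipped._backward = _bw
    n = probs.shape[0]
    return -(onehot * clipped.log()).sum() * Tensor(np.float32(1.0 / n))
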