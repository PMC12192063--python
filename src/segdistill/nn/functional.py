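"""Composite differentiable functions built from autograd primitives."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["softmax", "log_softmax", "cross_entropy", "soft_dice_loss"]


def softmax(x: Tensor, axis: int) -> Tensor:
    # max-shift is treated as a constant: almost-everywhere exact gradient
    m = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - m).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int) -> Tensor:
    m = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - m
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(
    logits: Tensor, target_index: np.ndarray, reduction: str = "mean"
) -> Tensor:
    """Pixelwise multiclass cross-entropy.

    logits: (B, K, H, W); target_index: (B, H, W) integer class map.
    reduction 'mean' averages over all pixels; 'per_sample' averages over the
    pixels of each sample and returns a (B,) tensor.
    """
    B, K, H, W = logits.shape
    logp = log_softmax(logits, axis=1)
    onehot = np.zeros((B, K, H, W), dtype=np.float32)
    np.put_along_axis(onehot, target_index[:, None, :, :], 1.0, axis=1)
    picked = logp * Tensor(onehot)
    if reduction == "mean":
        return -picked.sum() * (1.0 / (B * H * W))
    if reduction == "per_sample":
        return -picked.sum(axis=(1, 2, 3)) * (1.0 / (H * W))
    raise ValueError(f"unknown reduction {reduction!r}")


def soft_dice_loss(
    probs: Tensor,
    target_index: np.ndarray,
    foreground_classes: tuple[int, ...],
    eps: float = 1e-5,
    reduction: str = "mean",
) -> Tensor:
    """Sum over foreground classes of (1 - soft Dice).

    probs: (B, K, H, W) class probabilities; the soft Dice for class c uses
    the predicted probability map against the binary ground-truth mask with
    additive smoothing eps in numerator and denominator.
    """
    B = probs.shape[0]
    terms = []
    for c in foreground_classes:
        p = probs[:, c, :, :]
        t = Tensor((target_index == c).astype(np.float32))
        inter = (p * t).sum(axis=(1, 2))
        denom = p.sum(axis=(1, 2)) + t.sum(axis=(1, 2))
        dice = (2.0 * inter + eps) / (denom + eps)
        terms.append(1.0 - dice)  # (B,)
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    if reduction == "mean":
        return total.sum() * (1.0 / B)
    if reduction == "per_sample":
        return total
    raise ValueError(f"unknown reduction {reduction!r}")
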