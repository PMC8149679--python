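"""Segmentation losses: multi-label soft Dice plus focal loss.

Both operate on an S-channel logit map; probabilities come from a softmax
over the label axis. The soft Dice loss is

    1 - mean_s (2 * sum(p_s * g_s) + eps) / (sum(p_s) + sum(g_s) + eps)

with the smoothing term in numerator and denominator so a perfect one-hot
prediction scores exactly zero, and labels absent from both prediction and
ground truth contribute no loss. The focal loss is the mean over pixels of
``-(1 - p_t)**gamma * log(p_t)`` where ``p_t`` is the probability assigned
to the true label; at ``gamma = 0`` it reduces to cross-entropy.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "softmax",
    "soft_dice_loss",
    "focal_loss",
    "segmentation_loss",
    "segmentation_loss_grad",
    "total_loss",
]

_CLIP = 1e-12


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _one_hot(labels: np.ndarray, s: int) -> np.ndarray:
    if labels.min() < 0 or labels.max() >= s:
        raise ValueError(f"labels must lie in [0, {s})")
    return np.moveaxis(np.eye(s, dtype=np.float64)[labels], -1, 1)


def soft_dice_loss(logits: np.ndarray, labels: np.ndarray, eps: float = 1e-5) -> float:
    if logits.size == 0:
        raise ValueError("empty input")
    s = logits.shape[1]
    p = softmax(np.asarray(logits, dtype=np.float64))
    g = _one_hot(np.asarray(labels), s)
    num = 2.0 * (p * g).sum(axis=(0, 2, 3)) + eps
    den = p.sum(axis=(0, 2, 3)) + g.sum(axis=(0, 2, 3)) + eps
    return float(1.0 - np.mean(num / den))


def focal_loss(logits: np.ndarray, labels: np.ndarray, gamma: float = 2.0) -> float:
    if logits.size == 0:
        raise ValueError("empty input")
    p = softmax(np.asarray(logits, dtype=np.float64))
    s = p.shape[1]
    g = _one_hot(np.asarray(labels), s)
    pt = np.clip((p * g).sum(axis=1), _CLIP, 1.0)
    return float(np.mean(-((1.0 - pt) ** gamma) * np.log(pt)))


def segmentation_loss(logits: np.ndarray, labels: np.ndarray, *, gamma: float = 2.0,
                      eps: float = 1e-5) -> float:
    """Soft Dice loss plus focal loss."""
    return soft_dice_loss(logits, labels, eps=eps) + focal_loss(logits, labels, gamma=gamma)


def segmentation_loss_grad(logits: np.ndarray, labels: np.ndarray, *, gamma: float = 2.0,
                           eps: float = 1e-5) -> np.ndarray:
    """Analytic gradient of ``segmentation_loss`` with respect to the logits."""
    logits = np.asarray(logits)
    s = logits.shape[1]
    p = softmax(logits.astype(np.float64))
    g = _one_hot(np.asarray(labels), s)

    # soft Dice: d/dp_s(i) of -(1/S) * (2A_s + eps)/(B_s + eps)
    a = (p * g).sum(axis=(0, 2, 3))
    b = p.sum(axis=(0, 2, 3)) + g.sum(axis=(0, 2, 3))
    dl_dp = -(1.0 / s) * (
        2.0 * g / (b + eps)[None, :, None, None]
        - ((2.0 * a + eps) / (b + eps) ** 2)[None, :, None, None]
    )

    # focal: derivative only through the true-label probability. The floor is
    # looser than the forward clip so float32 squared gradients cannot overflow.
    npix = p.shape[0] * p.shape[2] * p.shape[3]
    pt = np.clip((p * g).sum(axis=1, keepdims=True), 1e-6, 1.0)
    if gamma == 0:
        dfdpt = -1.0 / pt
    else:
        dfdpt = gamma * (1.0 - pt) ** (gamma - 1.0) * np.log(pt) - (1.0 - pt) ** gamma / pt
    dl_dp = dl_dp + g * dfdpt / npix

    # chain through softmax: dL/dz = p * (dL/dp - sum_s p_s dL/dp_s)
    inner = (p * dl_dp).sum(axis=1, keepdims=True)
    return (p * (dl_dp - inner)).astype(logits.dtype)


def total_loss(latent_loss_value: float, segmentation_loss_value: float) -> float:
    """Overall training objective: latent loss plus segmentation loss."""
    out = float(latent_loss_value) + float(segmentation_loss_value)
    if not np.isfinite(out):
        raise FloatingPointError("non-finite total loss")
    return out
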