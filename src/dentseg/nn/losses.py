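"""Segmentation losses on logits: binary cross-entropy and soft Dice."""

from __future__ import annotations

import numpy as np

_EPS = 1.0


def sigmoid(z: np.ndarray) -> np.ndarray:
    # logits are clamped to +/-30: probabilities stay strictly inside
    # (0, 1) and, crucially, never underflow into float32 denormals,
    # which would stall downstream element-wise and BLAS kernels
    z = np.clip(z, -30.0, 30.0)
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out.astype(z.dtype)


def soft_dice(p: np.ndarray, y: np.ndarray, eps: float = _EPS) -> float:
    """Batch-global soft Dice coefficient with additive smoothing."""
    inter = float((p * y).sum())
    return (2.0 * inter + eps) / (float(p.sum()) + float(y.sum()) + eps)


def bce_dice_loss_and_grad(z: np.ndarray, y: np.ndarray,
                           kind: str = "bce_plus_dice"):
    """Loss value and its gradient w.r.t. the logits ``z``.

    ``kind`` is one of ``bce``, ``dice``, ``bce_plus_dice``. BCE is averaged
    per pixel; the Dice term is batch-global, which keeps its gradient
    well-scaled for very sparse masks.
    """
    p = sigmoid(z)
    n = z.size
    grad = np.zeros_like(z)
    loss = 0.0
    if kind in ("bce", "bce_plus_dice"):
        # stable log-sigmoid: log(1+e^z) - y*z averaged over pixels
        zc = np.clip(z, -60, 60).astype(np.float64)
        loss += float(np.mean(np.logaddexp(0.0, zc) - y * zc))
        grad += ((p - y) / n).astype(z.dtype)
    if kind in ("dice", "bce_plus_dice"):
        inter = float((p * y).sum())
        denom = float(p.sum()) + float(y.sum()) + _EPS
        dice = (2.0 * inter + _EPS) / denom
        loss += 1.0 - dice
        # d(1-D)/dp = -(2*y*denom - (2*inter+eps)) / denom^2, then * p(1-p)
        dD_dp = (2.0 * y * denom - (2.0 * inter + _EPS)) / (denom * denom)
        grad += (-dD_dp * p * (1.0 - p)).astype(z.dtype)
    if kind not in ("bce", "dice", "bce_plus_dice"):
        raise ValueError(f"unknown loss kind: {kind!r}")
    return loss, grad
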