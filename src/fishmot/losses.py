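"""Occlusion-head loss functions as standalone array math.

These are the numeric operations an occlusion-aware detection head trains
with: a focal loss over per-pixel occlusion probabilities, a Dice loss over
the predicted mask, a sign-driven adaptive reweighting of the two, and the
weighted total.  There is no autodiff and no training loop here — only the
losses themselves, usable on plain numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

_CLIP = 1e-7
_WEIGHT_FLOOR = 1e-8


@dataclass(frozen=True)
class LossWeights:
    """Focal/Dice mixing weights plus the overall occlusion-loss weight."""

    alpha: float = 0.5
    beta: float = 0.5
    w_base: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.w_base < 0:
            raise ValueError("w_base must be non-negative")


def _as_pair(p, y) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: predictions {p.shape} vs labels {y.shape}")
    return p, y


def focal_loss(pt, yt, *, label_aligned: bool = False) -> float:
    """Mean focal loss over occlusion probabilities ``pt`` and labels ``yt``.

    The default form modulates the full two-sided cross-entropy with a
    single (1 - pt)^2 factor.  With ``label_aligned=True`` the modulation
    uses the probability assigned to the true class instead (the common
    focal-loss formulation); both reduce to cross-entropy when the
    modulation factor is 1.
    """
    p, y = _as_pair(pt, yt)
    p = np.clip(p, _CLIP, 1.0 - _CLIP)
    ce = -(y * np.log(p) + (1.0 - y) * np.log1p(-p))
    if label_aligned:
        p_true = np.where(y > 0.5, p, 1.0 - p)
        mod = (1.0 - p_true) ** 2
    else:
        mod = (1.0 - p) ** 2
    return float(np.mean(mod * ce))


def dice_loss(p, y, eps: float = 1.0) -> float:
    """Smoothed Dice loss, 1 - (2 Σ p·y + eps) / (Σ p + Σ y + eps)."""
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    p, y = _as_pair(p, y)
    num = 2.0 * float(np.sum(p * y)) + eps
    den = float(np.sum(p)) + float(np.sum(y)) + eps
    return 1.0 - num / den


def adapt_weights(
    weights: LossWeights,
    grad_alpha: float,
    grad_beta: float,
    eta: float = 0.05,
) -> LossWeights:
    """Sign-driven update of the focal/Dice mixing weights.

    Each weight shrinks when its loss gradient is positive and grows when it
    is negative — a multiplicative step of size ``eta`` in the gradient-sign
    direction — then both are floored at 1e-8 and renormalised to sum to 1,
    keeping the two terms in balanced contribution.
    """
    if not (np.isfinite(grad_alpha) and np.isfinite(grad_beta)):
        raise ValueError("gradients must be finite")
    a = max(weights.alpha * (1.0 - eta * np.sign(grad_alpha)), _WEIGHT_FLOOR)
    b = max(weights.beta * (1.0 - eta * np.sign(grad_beta)), _WEIGHT_FLOOR)
    total = a + b
    return replace(weights, alpha=a / total, beta=b / total)


def total_loss(l_focal: float, l_dice: float, weights: LossWeights) -> float:
    """Overall occlusion loss: w_base · (α · L_focal + β · L_dice)."""
    if l_focal < 0 or l_dice < 0:
        raise ValueError("component losses must be non-negative")
    return weights.w_base * (weights.alpha * l_focal + weights.beta * l_dice)
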