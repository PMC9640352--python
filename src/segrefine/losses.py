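"""Overlap-based segmentation losses: Dice, generalized Dice, and Tversky.

These are framework-agnostic reference implementations operating on flat
numpy arrays of expected label values ``p`` and predicted values ``phat``,
both in [0, 1].  Soft (probabilistic) inputs are supported throughout; hard
binary labels are the special case, so the same code serves differentiable
training references and binary evaluation.

The Tversky index TI = TP / (TP + alpha*FP + beta*FN) generalizes Dice by
weighting false positives and false negatives asymmetrically; with
alpha = beta = 0.5 it reduces exactly to the Dice similarity coefficient.
Weighting false negatives more (beta > alpha) trades over-segmentation for
sensitivity, which matters when missed organ tissue is the costlier error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ComputationError, UsageError

logger = logging.getLogger(__name__)

__all__ = [
    "TverskyParams",
    "TVERSKY_PRESETS",
    "dice_loss",
    "generalized_dice_loss",
    "tversky_loss",
]


@dataclass(frozen=True)
class TverskyParams:
    """False-positive weight ``alpha`` and false-negative weight ``beta``.

    The weights must sum to 1 and satisfy beta >= alpha (beta == alpha == 0.5
    is the Dice limit).
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if abs(self.alpha + self.beta - 1.0) > 1e-12:
            raise UsageError(f"alpha + beta must equal 1, got {self.alpha} + {self.beta}")
        if self.beta < self.alpha:
            raise UsageError(f"beta must be >= alpha, got alpha={self.alpha}, beta={self.beta}")


#: Named (alpha, beta) grid points used when comparing loss variants.
TVERSKY_PRESETS: dict[str, TverskyParams] = {
    "TL46": TverskyParams(0.4, 0.6),
    "TL37": TverskyParams(0.3, 0.7),
    "TL28": TverskyParams(0.2, 0.8),
    "TL19": TverskyParams(0.1, 0.9),
}


def _check_pair(p, phat) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64).ravel()
    phat = np.asarray(phat, dtype=np.float64).ravel()
    if p.shape != phat.shape:
        raise UsageError(f"length mismatch: {p.size} vs {phat.size}")
    for name, arr in (("p", p), ("phat", phat)):
        if arr.size and (arr.min() < 0 or arr.max() > 1):
            raise UsageError(f"{name} values must lie in [0, 1]")
    return p, phat


def dice_loss(p, phat, eps: float = 1e-6) -> float:
    """Dice loss 1 - (2*sum(p*phat) + eps) / (sum(p^2) + sum(phat^2) + eps)."""
    p, phat = _check_pair(p, phat)
    num = 2.0 * float(np.dot(p, phat)) + eps
    den = float(np.dot(p, p)) + float(np.dot(phat, phat)) + eps
    return 1.0 - num / den


def generalized_dice_loss(p, phat, weight: str = "prediction") -> float:
    """Generalized Dice loss over K classes.

    ``p`` and ``phat`` are (K, N) arrays (a single 1D pair is treated as
    K = 1).  The per-class weight is ``1 / sum(phat_l)`` with
    ``weight="prediction"`` (the form used here by default); the conventional
    alternative ``1 / sum(p_l)**2`` is available as ``weight="gt_squared"``.
    Classes whose weight denominator is zero contribute nothing and are
    logged; if every class is empty the score is undefined.
    """
    p = np.atleast_2d(np.asarray(p, dtype=np.float64))
    phat = np.atleast_2d(np.asarray(phat, dtype=np.float64))
    if p.shape != phat.shape:
        raise UsageError(f"shape mismatch: {p.shape} vs {phat.shape}")
    if weight not in ("prediction", "gt_squared"):
        raise UsageError(f"weight must be 'prediction' or 'gt_squared', got {weight!r}")

    num = 0.0
    den = 0.0
    for l in range(p.shape[0]):
        pl, pl_hat = _check_pair(p[l], phat[l])
        wden = float(pl_hat.sum()) if weight == "prediction" else float(pl.sum()) ** 2
        if wden == 0.0:
            logger.warning("generalized_dice_loss: class %d has zero weight denominator, skipped", l)
            continue
        w = 1.0 / wden
        num += w * float(np.dot(pl, pl_hat))
        den += w * float((pl + pl_hat).sum())
    if den == 0.0:
        raise ComputationError("generalized Dice undefined: all classes empty")
    return 1.0 - 2.0 * num / den


def tversky_loss(p, phat, params: TverskyParams, eps: float = 1e-6) -> float:
    """Tversky loss 1 - (TP + eps) / (TP + alpha*FP + beta*FN + eps).

    Soft counts TP = sum(p*phat), FP = sum((1-p)*phat), FN = sum(p*(1-phat));
    on binary inputs these are the usual confusion counts.
    """
    p, phat = _check_pair(p, phat)
    tp = float(np.dot(p, phat))
    fp = float(np.dot(1.0 - p, phat))
    fn = float(np.dot(p, 1.0 - phat))
    return 1.0 - (tp + eps) / (tp + params.alpha * fp + params.beta * fn + eps)
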