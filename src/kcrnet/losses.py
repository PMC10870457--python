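"""Focal loss for imbalanced binary classification.

For a sample with positive-class probability p and label y,

    pt = p        if y = 1          at = alpha      if y = 1
         1 - p    otherwise              1 - alpha  otherwise

    FL = -at * (1 - pt)^gamma * ln(pt)

With gamma = 0 and alpha = 0.5 this is half the standard cross-entropy; the
modulating factor (1 - pt)^gamma down-weights well-classified samples so
training emphasizes the hard ones, and alpha re-balances the classes.
Defaults are alpha = 0.7, gamma = 1.  Probabilities are clamped to
[eps, 1 - eps] with eps = 1e-7 before the logarithm; the clamp value is a
numerical guard, not part of the loss definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FocalLossParams", "focal_loss", "focal_loss_grad"]

EPS = 1e-7


@dataclass(frozen=True)
class FocalLossParams:
    alpha: float = 0.7
    gamma: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.gamma < 0.0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")


def _validate(p: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y)
    if p.shape != y.shape:
        raise ValueError(f"p and y have mismatched shapes {p.shape} vs {y.shape}")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    return p, y.astype(np.float64)


def focal_loss(
    p: np.ndarray, y: np.ndarray, params: FocalLossParams = FocalLossParams()
) -> tuple[np.ndarray, float]:
    """Per-sample focal losses and their batch mean."""
    p, y = _validate(p, y)
    pt = np.where(y == 1, p, 1.0 - p)
    at = np.where(y == 1, params.alpha, 1.0 - params.alpha)
    pt = np.clip(pt, EPS, 1.0 - EPS)
    per_sample = -at * (1.0 - pt) ** params.gamma * np.log(pt)
    return per_sample, float(per_sample.mean())


def focal_loss_grad(
    p: np.ndarray, y: np.ndarray, params: FocalLossParams = FocalLossParams()
) -> np.ndarray:
    """Analytic d(per-sample loss)/dp.

    d/dpt [-at (1-pt)^g ln pt] = at * (g (1-pt)^(g-1) ln pt - (1-pt)^g / pt),
    and dpt/dp = +1 for y=1, -1 for y=0.  Zero where the clamp is active.
    """
    p, y = _validate(p, y)
    a, g = params.alpha, params.gamma
    pt_raw = np.where(y == 1, p, 1.0 - p)
    pt = np.clip(pt_raw, EPS, 1.0 - EPS)
    at = np.where(y == 1, a, 1.0 - a)
    one_minus = 1.0 - pt
    if g == 0.0:
        dpt = -at / pt
    else:
        dpt = at * (g * one_minus ** (g - 1.0) * np.log(pt) - one_minus**g / pt)
    dpt = np.where((pt_raw >= EPS) & (pt_raw <= 1.0 - EPS), dpt, 0.0)
    return np.where(y == 1, dpt, -dpt)
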