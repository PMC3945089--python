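"""Weighted Pattern Generating Potential (w-PGP).

w-PGP compares a predicted spatial expression profile against the real one
by rewarding correctly predicted expression and penalising erroneous
(over-) expression, each normalised so both terms live in [0, 1]:

    reward  = sum_i min(p_i, r_i) * r_i / sum_i r_i^2
    penalty = sum_i max(p_i - r_i, 0) * (1 - r_i) / sum_i (1 - r_i)^2
    score   = clamp(reward - penalty, 0, 1)

The reward weights each bin by the real level (getting strong expression
right matters most); the penalty weights over-expression by the available
headroom (predicting expression where there is none is worst). It replaces
sum-of-squared-errors / correlation objectives, which miss salient features
of striped profiles. Both profiles must be on one grid and scaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AxisProfile

_EPS = 1e-9


@dataclass(frozen=True)
class WpgpBreakdown:
    reward: float
    penalty: float
    score: float


def wpgp_arrays(pred: np.ndarray, real: np.ndarray) -> WpgpBreakdown:
    """w-PGP of two bare value arrays on a shared grid."""
    pred = np.asarray(pred, dtype=float)
    real = np.asarray(real, dtype=float)
    if pred.shape != real.shape:
        raise ValueError("profiles must share one grid")
    for name, v in (("pred", pred), ("real", real)):
        if v.min() < -_EPS or v.max() > 1 + _EPS:
            raise ValueError(f"{name} profile values must lie in [0, 1]")
    pred = np.clip(pred, 0.0, 1.0)
    real = np.clip(real, 0.0, 1.0)

    r_sq = float(np.sum(real * real))
    if r_sq > 0:
        reward = float(np.sum(np.minimum(pred, real) * real)) / r_sq
    else:  # no real expression anywhere: only an all-zero prediction is correct
        reward = 1.0 if np.all(pred <= _EPS) else 0.0

    head_sq = float(np.sum((1.0 - real) ** 2))
    if head_sq > 0:
        over = np.maximum(pred - real, 0.0)
        penalty = float(np.sum(over * (1.0 - real))) / head_sq
    else:  # real profile saturated everywhere: over-expression impossible
        penalty = 0.0

    score = min(max(reward - penalty, 0.0), 1.0)
    return WpgpBreakdown(reward, penalty, score)


def wpgp(pred: AxisProfile, real: AxisProfile) -> WpgpBreakdown:
    """w-PGP of two axis profiles (must share one grid)."""
    if not pred.same_grid(real):
        raise ValueError("profiles must share one axis grid")
    return wpgp_arrays(pred.values, real.values)


def wpgp_score(pred, real) -> float:
    """Shorthand for the scalar score of :func:`wpgp_arrays`."""
    return wpgp_arrays(
        pred.values if isinstance(pred, AxisProfile) else pred,
        real.values if isinstance(real, AxisProfile) else real,
    ).score


def mean_wpgp(pairs) -> float:
    """Arithmetic mean of per-pair w-PGP scores."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one (pred, real) pair")
    return float(np.mean([wpgp_score(p, r) for p, r in pairs]))


def rmse(pred, real) -> float:
    """Root-mean-square error (debug/diagnostic output only, never an objective)."""
    p = pred.values if isinstance(pred, AxisProfile) else np.asarray(pred, float)
    r = real.values if isinstance(real, AxisProfile) else np.asarray(real, float)
    return float(np.sqrt(np.mean((p - r) ** 2)))
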