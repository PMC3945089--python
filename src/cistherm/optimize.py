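"""Shared numerical maximiser: alternating simplex / bounded quasi-Newton.

All model fitting in the package maximises a w-PGP objective that is
piecewise smooth (clipping and the clamp at 0/1 introduce kinks), so a
derivative-free simplex pass is alternated with bounded L-BFGS-B using
numerical gradients, optionally from several seeded random restarts inside
the feasible box. Deterministic given the seed.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize as sopt


def _clip_to_bounds(x: np.ndarray, bounds) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return np.clip(x, lo, hi)


def alternating_maximize(
    fun,
    x0: np.ndarray,
    bounds,
    seed: int = 0,
    n_restarts: int = 0,
    rounds: int = 2,
    nm_maxiter: int = 200,
    lbfgs_maxiter: int = 60,
    tol: float = 1e-6,
):
    """Maximise ``fun`` over the box ``bounds`` starting from ``x0``.

    Runs ``rounds`` alternations of Nelder-Mead (clipped to the box) and
    L-BFGS-B per start point; ``n_restarts`` extra start points are drawn
    uniformly inside the box. Returns the best x found.
    """
    x0 = _clip_to_bounds(np.asarray(x0, dtype=float), bounds)
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def neg(x):
        return -fun(_clip_to_bounds(x, bounds))

    starts = [x0]
    for _ in range(n_restarts):
        starts.append(lo + rng.random(len(bounds)) * (hi - lo))

    best_x, best_f = x0, fun(x0)
    for start in starts:
        x = start
        f_prev = -neg(x)
        for _ in range(rounds):
            res = sopt.minimize(
                neg, x, method="Nelder-Mead",
                options={"maxiter": nm_maxiter, "xatol": 1e-8, "fatol": tol},
            )
            x = _clip_to_bounds(res.x, bounds)
            res = sopt.minimize(
                neg, x, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": lbfgs_maxiter, "ftol": tol},
            )
            x = _clip_to_bounds(res.x, bounds)
            f_now = -res.fun
            if abs(f_now - f_prev) < tol:
                break
            f_prev = f_now
        f = fun(x)
        if f > best_f:
            best_x, best_f = x, f
    return best_x


def maximize_nonnegative(fun, x0: np.ndarray, rounds: int = 2,
                         nm_maxiter: int = 200, lbfgs_maxiter: int = 80,
                         tol: float = 1e-8) -> np.ndarray:
    """Maximise over the nonnegative orthant (window-weight fitting)."""
    bounds = [(0.0, None)] * len(x0)

    def neg(x):
        return -fun(np.maximum(x, 0.0))

    x = np.maximum(np.asarray(x0, dtype=float), 0.0)
    f_prev = -neg(x)
    for _ in range(rounds):
        res = sopt.minimize(
            neg, x, method="Nelder-Mead",
            options={"maxiter": nm_maxiter, "xatol": 1e-9, "fatol": tol},
        )
        x = np.maximum(res.x, 0.0)
        res = sopt.minimize(
            neg, x, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": lbfgs_maxiter, "ftol": tol},
        )
        x = np.maximum(res.x, 0.0)
        f_now = -res.fun
        if abs(f_now - f_prev) < tol:
            break
        f_prev = f_now
    return x
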