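"""Derivative-free coefficient optimization.

The ranking-quality objective is piecewise constant in the coefficients (it
changes only when two instances swap rank), so gradient methods are useless.
Coefficients are optimized with the classic Hooke-Jeeves pattern search
(exploratory axis moves plus pattern extrapolation), seeded from uniform
random starts scaled by the reciprocal descriptor standard deviations so that
raw, wildly differently scaled descriptors contribute comparably to the
initial scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["HookeJeevesResult", "hooke_jeeves", "random_starts", "default_step"]


@dataclass
class HookeJeevesResult:
    x: np.ndarray
    fun: float
    iterations: int
    converged: bool  # False when the iteration budget ran out first


def default_step(x0: np.ndarray, fraction: float = 0.25, floor: float = 0.1) -> np.ndarray:
    """Initial exploratory step: 0.25*|x0_j| with a floor of 0.1 per axis."""
    return np.maximum(fraction * np.abs(np.asarray(x0, dtype=float)), floor)


def _explore(f: Callable, x: np.ndarray, fx: float, step: np.ndarray):
    """One exploratory pass: per axis, try +step then -step, keep improvements."""
    x = x.copy()
    for j in range(len(x)):
        xj = x[j]
        x[j] = xj + step[j]
        fp = f(x)
        if fp > fx:
            fx = fp
            continue
        x[j] = xj - step[j]
        fm = f(x)
        if fm > fx:
            fx = fm
            continue
        x[j] = xj
    return x, fx


def hooke_jeeves(
    objective: Callable[[np.ndarray], float],
    x0,
    step0=None,
    iterations: int = 5000,
    rms_tol: float = 0.001,
) -> HookeJeevesResult:
    """Maximize ``objective`` by Hooke-Jeeves pattern search.

    Exploratory moves probe each axis at +-step; on success a pattern move
    extrapolates along the improving direction.  A failed exploration halves
    every step; the search terminates when the RMS of the step vector drops
    below ``rms_tol`` or the iteration budget is exhausted (the latter is a
    normal termination, flagged via ``converged=False``).  The returned point
    is the best seen, so ``fun >= objective(x0)`` always holds.
    """
    x_base = np.asarray(x0, dtype=float).copy()
    if x_base.ndim != 1:
        raise ValueError("x0 must be a 1-D vector")
    step = (
        default_step(x_base) if step0 is None else np.asarray(step0, float).copy()
    )
    if step.shape != x_base.shape or (step <= 0).any():
        raise ValueError("step0 must be positive and match x0's shape")
    f_base = float(objective(x_base))

    it = 0
    converged = False
    while it < iterations:
        it += 1
        x_new, f_new = _explore(objective, x_base, f_base, step)
        if f_new > f_base:
            # pattern moves: extrapolate while the exploration keeps improving
            while it < iterations:
                it += 1
                x_pat = x_new + (x_new - x_base)
                x_base, f_base = x_new, f_new
                f_pat = float(objective(x_pat))
                x_try, f_try = _explore(objective, x_pat, f_pat, step)
                if f_try > f_base:
                    x_new, f_new = x_try, f_try
                else:
                    break
            x_base, f_base = x_new, f_new
        else:
            step = step / 2.0
            if float(np.sqrt(np.mean(step * step))) < rms_tol:
                converged = True
                break
    return HookeJeevesResult(x=x_base, fun=f_base, iterations=it, converged=converged)


def random_starts(
    k: int,
    cycles: int,
    rng: np.random.Generator,
    scales=None,
) -> np.ndarray:
    """Random starting coefficient vectors for the pattern search.

    Each of the ``cycles`` vectors has coordinates uniform in [-1, 1],
    rescaled by 1/sigma_j where sigma_j is the sample standard deviation of
    variable j (``scales``).  Descriptors are used raw and can span many
    orders of magnitude; the rescaling makes each variable's initial score
    contribution comparable without touching the data.  A zero-variance
    variable gets scale factor 1.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    raw = rng.uniform(-1.0, 1.0, size=(cycles, k))
    if scales is None:
        return raw
    scales = np.asarray(scales, dtype=float).copy()
    if scales.shape != (k,):
        raise ValueError("scales must have length k")
    scales[scales <= 0] = 1.0
    return raw / scales
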