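"""Penalized derivative-free minimization shared by all fitting workflows.

The contract is a Nelder-Mead simplex search on a smooth objective augmented
with a quadratic out-of-bounds penalty, plus seeded multi-start jitter; no
gradient-based or global optimizers are used anywhere in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

__all__ = ["bound_penalty", "penalized_objective", "minimize", "OptimizeOutcome"]

PENALTY_SCALE = 1e6


def _bound_width(lo: float, hi: float) -> float:
    if math.isfinite(lo) and math.isfinite(hi) and hi > lo:
        return hi - lo
    return max(1.0, abs(lo) if math.isfinite(lo) else 0.0, abs(hi) if math.isfinite(hi) else 0.0)


def bound_penalty(x: np.ndarray, bounds: Sequence[tuple[float, float]] | None,
                  scale: float = PENALTY_SCALE) -> float:
    """Quadratic penalty on normalized bound violations; exactly 0 inside bounds."""
    if bounds is None:
        return 0.0
    total = 0.0
    for value, (lo, hi) in zip(x, bounds):
        width = _bound_width(lo, hi)
        if value < lo:
            total += ((lo - value) / width) ** 2
        elif value > hi:
            total += ((value - hi) / width) ** 2
    return scale * total


def penalized_objective(objective: Callable[[np.ndarray], float], params,
                        bounds: Sequence[tuple[float, float]] | None,
                        scale: float = PENALTY_SCALE) -> float:
    """Objective value plus the out-of-bounds penalty at ``params``."""
    x = np.asarray(params, dtype=float)
    return float(objective(x)) + bound_penalty(x, bounds, scale)


@dataclass
class OptimizeOutcome:
    x: np.ndarray
    fun: float
    n_evals: int
    converged: bool
    seed: int
    n_restarts: int
    all_fun: list[float] = field(default_factory=list)


def minimize(
    fun: Callable[[np.ndarray], float],
    start: Sequence[float],
    *,
    bounds: Sequence[tuple[float, float]] | None = None,
    seed: int = 0,
    n_restarts: int = 5,
    jitter: float = 0.2,
    max_evals: int | None = None,
    xtol: float = 1e-8,
    ftol: float = 1e-10,
    n_polish: int = 3,
) -> OptimizeOutcome:
    """Seeded multi-start Nelder-Mead on an (already penalized) objective.

    Deterministic given ``start``, ``seed`` and the options.  The search runs
    in a space scaled by ``|start|`` so the simplex tolerances are relative.
    Restarts beyond the first jitter the start multiplicatively and are
    clipped into ``bounds`` when given.  The best restart is returned;
    ``converged`` is False only if every restart exhausted its evaluation
    budget.
    """
    x0 = np.asarray(start, dtype=float)
    if not np.all(np.isfinite(x0)):
        raise ValueError("start point must be finite")
    scale = np.where(np.abs(x0) > 0, np.abs(x0), 1.0)
    if max_evals is None:
        max_evals = 2000 * x0.size

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(0, n_restarts - 1)):
        candidate = x0 * (1.0 + jitter * rng.standard_normal(x0.size))
        candidate += jitter * scale * 0.01 * rng.standard_normal(x0.size)  # escape exact zeros
        if bounds is not None:
            lo = np.array([b[0] for b in bounds])
            hi = np.array([b[1] for b in bounds])
            candidate = np.clip(candidate, lo, hi)
        starts.append(candidate)

    best = None
    any_converged = False
    total_evals = 0
    all_fun: list[float] = []
    for s in starts:
        result = _scipy_minimize(
            lambda z: fun(z * scale),
            s / scale,
            method="Nelder-Mead",
            options={
                "maxfev": max_evals,
                "xatol": xtol,
                "fatol": ftol,
                "adaptive": x0.size > 4,
            },
        )
        total_evals += result.nfev
        any_converged = any_converged or bool(result.success)
        all_fun.append(float(result.fun))
        if best is None or result.fun < best.fun:
            best = result
    assert best is not None

    # The simplex can stall in narrow valleys; restarting it from its own
    # best point recovers quickly.  Polish until the improvement is negligible.
    for _ in range(n_polish):
        result = _scipy_minimize(
            lambda z: fun(z * scale),
            best.x,
            method="Nelder-Mead",
            options={
                "maxfev": max_evals,
                "xatol": xtol,
                "fatol": ftol,
                "adaptive": x0.size > 4,
            },
        )
        total_evals += result.nfev
        improvement = best.fun - result.fun
        if result.fun < best.fun:
            any_converged = any_converged or bool(result.success)
            best = result
        if improvement <= max(ftol, 1e-8 * abs(best.fun)):
            break

    return OptimizeOutcome(
        x=best.x * scale,
        fun=float(best.fun),
        n_evals=total_evals,
        converged=any_converged,
        seed=seed,
        n_restarts=len(starts),
        all_fun=all_fun,
    )
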