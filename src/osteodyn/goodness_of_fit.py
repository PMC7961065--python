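"""Fit diagnostics (R², #R<1) and activity fold-range analysis.

Both R² and the residual count are computed against replicate means at the
post-baseline time points: day 0 is the imposed initial condition of every
simulation, not a fitted point.  The convention is recorded in the output
metadata wherever these diagnostics are serialized.

The fold range max(rate)/min(rate) of a per-cell activity time course is the
headline summary of how much remodeling activity must vary over the injury
response; a constant-activity model has fold range exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import PiecewiseRateFunction

__all__ = [
    "ActivityTimecourse",
    "FlatDataError",
    "r_squared",
    "count_residuals_below_one",
    "fold_range",
    "activity_from_fit",
]


class FlatDataError(ValueError):
    """R² is undefined when the data have zero variance around their mean."""


@dataclass(frozen=True)
class ActivityTimecourse:
    """Per-cell remodeling activity on a dense time grid."""

    times: np.ndarray
    rate: np.ndarray
    kind: str  # "resorption" | "formation"

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "rate", np.asarray(self.rate, dtype=float))
        if self.kind not in ("resorption", "formation"):
            raise ValueError("kind must be 'resorption' or 'formation'")
        if self.times.shape != self.rate.shape:
            raise ValueError("times and rate must have matching shapes")
        if not np.all(np.isfinite(self.rate)) or np.any(self.rate < 0):
            raise ValueError("activity rate must be finite and >= 0 everywhere")


def _aligned(predictions, data, variable: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(predictions, dict):
        f = np.asarray(predictions[variable], dtype=float)
    else:
        f = np.asarray(predictions, dtype=float)
    d = data.mean(variable)
    s = data.sigma(variable)
    if f.shape != d.shape:
        raise ValueError(
            f"predictions for {variable!r} have shape {f.shape}, data have {d.shape}"
        )
    post = data.times > 0
    return f[post], d[post], s[post]


def r_squared(predictions, data, variable: str) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot on post-baseline means.

    May be negative for fits worse than the data mean.  Raises
    :class:`FlatDataError` for flat data (zero total sum of squares).
    """
    f, d, _ = _aligned(predictions, data, variable)
    ss_res = float(np.sum((d - f) ** 2))
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    if ss_tot == 0.0:
        raise FlatDataError(f"variable {variable!r} is flat: R^2 undefined")
    return 1.0 - ss_res / ss_tot


def count_residuals_below_one(predictions, data, variable: str) -> tuple[int, int]:
    """Count post-baseline time points with |f(t_i) - D_i| / σ_i < 1 (strict)."""
    f, d, s = _aligned(predictions, data, variable)
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("standardized residuals need a positive sigma at every point")
    standardized = np.abs(f - d) / s
    return int(np.sum(standardized < 1.0)), int(standardized.size)


def fold_range(tc: ActivityTimecourse) -> float:
    """max(rate)/min(rate) over the time course; scale-invariant."""
    r_min = float(tc.rate.min())
    r_max = float(tc.rate.max())
    if r_min <= 0.0:
        raise ValueError("fold range is infinite for a rate touching zero")
    return r_max / r_min


def activity_from_fit(
    fit, pro_driver=None, anti_driver=None, t_grid=None
) -> tuple[ActivityTimecourse, ActivityTimecourse]:
    """Resorption and formation activity time courses implied by a bone fit.

    For a modulation fit these are ``delta_B * (1 + alpha * P(t))`` and
    ``Pi_B * (1 + beta * A(t))``; for a piecewise fit the fitted rate function
    is evaluated directly (the complementary rate is the constant recorded
    with the fit).
    """
    if t_grid is None:
        t_grid = np.linspace(0.0, 14.0, 1401)
    t_grid = np.asarray(t_grid, dtype=float)

    if fit.workflow == "modulation":
        if pro_driver is None or anti_driver is None:
            raise ValueError("modulation activities need the driver curves")
        P = np.asarray(pro_driver(t_grid), dtype=float)
        A = np.asarray(anti_driver(t_grid), dtype=float)
        res = fit.params["delta_B"] * (1.0 + fit.params["alpha"] * P)
        form = fit.meta["Pi_B"] * (1.0 + fit.params["beta"] * A)
        return (
            ActivityTimecourse(t_grid, res, "resorption"),
            ActivityTimecourse(t_grid, form, "formation"),
        )
    if fit.workflow == "piecewise":
        from .calibration import piecewise_from_fit

        fn: PiecewiseRateFunction = piecewise_from_fit(fit)
        varying = np.asarray(fn(t_grid), dtype=float)
        constant = np.full_like(t_grid, fit.meta["fixed_other_rate"])
        if fit.meta["which"] == "resorption":
            return (
                ActivityTimecourse(t_grid, varying, "resorption"),
                ActivityTimecourse(t_grid, constant, "formation"),
            )
        return (
            ActivityTimecourse(t_grid, constant, "resorption"),
            ActivityTimecourse(t_grid, varying, "formation"),
        )
    if fit.workflow in ("scan", "free_rates"):
        delta_B = fit.params["delta_B"]
        Pi_B = fit.params.get("Pi_B", fit.fixed.get("Pi_B"))
        return (
            ActivityTimecourse(t_grid, np.full_like(t_grid, delta_B), "resorption"),
            ActivityTimecourse(t_grid, np.full_like(t_grid, Pi_B), "formation"),
        )
    raise ValueError(f"no activity definition for workflow {fit.workflow!r}")
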