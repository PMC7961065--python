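"""Minimax weighted least-squares calibration of the bone-repair models.

The objective is the worst variable-wise weighted sum of squared residuals

    LS = max_j  Σ_i (f_j(t_i) - D_ij)^2 / σ_i^2

minimized so that no variable's fit is sacrificed to the benefit of another.
Minimization is a penalized Nelder-Mead simplex search (see ``_optimize``);
model comparison uses ``AIC = 2p + LS`` with ``p`` the number of free
parameters.

Fitting is staged exactly as the study design dictates: osteoblast and
osteoclast dynamics are calibrated first (bone excluded), then frozen while
the bone equation is fitted by one of four workflows — a closure-constrained
scan of constant resorption rates, a free joint fit of constant resorption
and formation rates, the myeloid-modulated fit of (delta_B, alpha, beta), and
the piecewise-linear time-varying rate fit.  There is no global refit.

For the bone stages the frozen cell dynamics are evaluated in closed form and
the scalar (linear) bone ODE is integrated with an exponential-midpoint
scheme on a fixed fine grid, which is fast, unconditionally stable and
accurate to O(dt^2).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import goodness_of_fit as gof
from ._optimize import OptimizeOutcome, bound_penalty, minimize, penalized_objective
from .model_core import (
    HomeostaticBaseline,
    InitialModelParameters,
    PiecewiseRateFunction,
    cell_trajectories,
)

__all__ = [
    "TimeSeriesDataset",
    "FitResult",
    "BootstrapResult",
    "CalibrationError",
    "objective_LS",
    "penalized_objective",
    "bound_penalty",
    "minimize",
    "aic",
    "calibrate_cell_dynamics",
    "scan_constant_rates",
    "fit_free_constant_rates",
    "fit_modulation",
    "fit_piecewise_rate",
    "bootstrap_se",
    "predictions_from_fit",
    "piecewise_from_fit",
    "MODEL_VARIABLES",
    "MYELOID_VARIABLES",
    "PUBLISHED_RESORPTION_RANGE",
    "TABLE_DELTA_OB",
    "TABLE_T_CATAB",
]

MODEL_VARIABLES = ("OB", "OC", "B")
MYELOID_VARIABLES = ("pro_mono", "pro_mac", "anti_mac", "anti_mono")
ALL_VARIABLES = MODEL_VARIABLES + MYELOID_VARIABLES

#: Published per-cell resorption-rate range (mm^3 cell^-1 day^-1).
PUBLISHED_RESORPTION_RANGE = (1e-8, 5e-5)
#: Literature-fixed osteoblast clearance rate (day^-1).
TABLE_DELTA_OB = 0.19
#: Imposed catabolism start time (days).
TABLE_T_CATAB = 2.0

_BONE_GRID_DT = 0.01


class CalibrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Dataset


class TimeSeriesDataset:
    """Sparse replicated observations with per-time-point error.

    Holds the raw long-format replicate table (``variable, time_day,
    replicate, value``) and derives, per variable, the replicate means
    ``D_ij`` and the experimental error ``σ_i`` (standard error of the mean,
    floored at ``sigma_floor_frac`` of the variable's baseline magnitude so a
    noise-free dataset never yields an undefined objective).
    """

    def __init__(self, table: pd.DataFrame, *, sigma_floor_frac: float = 0.05):
        required = {"variable", "time_day", "replicate", "value"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"dataset table lacks columns: {sorted(missing)}")
        if len(table) == 0:
            raise ValueError("dataset table is empty")
        table = table.copy()
        table["time_day"] = table["time_day"].astype(float)
        table["value"] = table["value"].astype(float)
        if (table["value"] < 0).any():
            bad = table.index[table["value"] < 0][0]
            raise ValueError(f"negative value at table row {bad}")
        self.table = table.sort_values(["variable", "time_day", "replicate"]).reset_index(drop=True)
        self.sigma_floor_frac = float(sigma_floor_frac)
        self.times = np.array(sorted(table["time_day"].unique()))
        if self.times[0] != 0.0:
            raise ValueError("dataset must include time 0 (baseline defines initial conditions)")
        self.variables = sorted(table["variable"].unique())
        grouped = self.table.groupby(["variable", "time_day"])["value"]
        self._means = grouped.mean().unstack(level="time_day")
        counts = grouped.count().unstack(level="time_day")
        std = grouped.std(ddof=1).unstack(level="time_day")
        sem = std / np.sqrt(counts)
        self._sigmas = {}
        for var in self.variables:
            means = self._means.loc[var].reindex(self.times).to_numpy()
            raw = sem.loc[var].reindex(self.times).to_numpy()
            base = abs(means[0])
            ref = base if base > 0 else (np.nanmax(np.abs(means)) or 1.0)
            floor = self.sigma_floor_frac * ref
            sigma = np.where(np.isfinite(raw), np.maximum(raw, floor), floor)
            self._sigmas[var] = sigma

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        times: Sequence[float],
        values: Mapping[str, np.ndarray],
        *,
        sigma_floor_frac: float = 0.05,
    ) -> "TimeSeriesDataset":
        """Build from per-variable arrays of shape (n_times, n_replicates)."""
        rows = []
        for var, mat in values.items():
            mat = np.atleast_2d(np.asarray(mat, dtype=float))
            for i, t in enumerate(times):
                for r in range(mat.shape[1]):
                    rows.append((var, float(t), r + 1, float(mat[i, r])))
        return cls(
            pd.DataFrame(rows, columns=["variable", "time_day", "replicate", "value"]),
            sigma_floor_frac=sigma_floor_frac,
        )

    # -- accessors ----------------------------------------------------------

    def mean(self, variable: str) -> np.ndarray:
        return self._means.loc[variable].reindex(self.times).to_numpy()

    def sigma(self, variable: str) -> np.ndarray:
        return self._sigmas[variable].copy()

    def baseline_value(self, variable: str) -> float:
        return float(self.mean(variable)[0])

    def baseline(self, default_B: float = 1.0) -> HomeostaticBaseline:
        """Homeostatic baseline from the day-0 replicate means."""
        return HomeostaticBaseline(
            OB_0=self.baseline_value("OB") if "OB" in self.variables else 1.0,
            OC_0=self.baseline_value("OC") if "OC" in self.variables else 1.0,
            B_0=self.baseline_value("B") if "B" in self.variables else default_B,
        )

    def subset(self, variables: Iterable[str]) -> "TimeSeriesDataset":
        variables = list(variables)
        sub = self.table[self.table["variable"].isin(variables)]
        return TimeSeriesDataset(sub, sigma_floor_frac=self.sigma_floor_frac)

    def resample(self, rng: np.random.Generator) -> "TimeSeriesDataset":
        """Parametric-bootstrap resample: replicates drawn with replacement
        independently at every (variable, time point)."""
        parts = []
        for (var, t), group in self.table.groupby(["variable", "time_day"]):
            values = group["value"].to_numpy()
            draw = rng.choice(values, size=values.size, replace=True)
            parts.append(
                pd.DataFrame(
                    {
                        "variable": var,
                        "time_day": t,
                        "replicate": np.arange(1, values.size + 1),
                        "value": draw,
                    }
                )
            )
        return TimeSeriesDataset(pd.concat(parts, ignore_index=True),
                                 sigma_floor_frac=self.sigma_floor_frac)

    def to_long(self) -> pd.DataFrame:
        return self.table.copy()


# ---------------------------------------------------------------------------
# Objective and information criterion


def objective_LS(
    model_evaluator: Callable,
    params,
    data: TimeSeriesDataset,
    variables: Sequence[str] | None = None,
) -> tuple[float, dict[str, float]]:
    """Minimax weighted least squares.

    ``model_evaluator(params)`` must return a mapping variable -> predictions
    aligned with ``data.times``.  Returns ``(LS, per_variable_inner_sums)``
    where ``LS`` is the maximum inner sum over the fitted variables.
    """
    preds = model_evaluator(params)
    use = list(variables) if variables is not None else list(data.variables)
    per_variable: dict[str, float] = {}
    for var in use:
        if var not in preds:
            raise CalibrationError(f"model evaluator produced no prediction for {var!r}")
        f = np.asarray(preds[var], dtype=float)
        d = data.mean(var)
        if f.shape != d.shape:
            raise CalibrationError(
                f"prediction for {var!r} has shape {f.shape}, data has {d.shape}"
            )
        resid = (f - d) / data.sigma(var)
        per_variable[var] = float(np.nansum(resid**2))
    return max(per_variable.values()), per_variable


def aic(p: int, LS: float) -> float:
    """Information criterion ``AIC = 2p + LS``."""
    if p < 0:
        raise ValueError("parameter count must be >= 0")
    return 2.0 * p + LS


# ---------------------------------------------------------------------------
# Fit result


@dataclass
class FitResult:
    """Complete record of one fitting workflow, sufficient to re-simulate."""

    workflow: str
    params: dict[str, float]
    fixed: dict[str, float]
    baseline: HomeostaticBaseline
    LS: float
    AIC: float
    per_variable_SS: dict[str, float]
    r_squared: dict[str, float]
    n_residuals_below_one: dict[str, tuple[int, int]]
    converged: bool
    n_evals: int
    seed: int
    bounds: dict[str, tuple[float, float]]
    se: dict[str, float] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_free(self) -> int:
        return len(self.params)

    def to_dict(self) -> dict:
        return {
            "workflow": self.workflow,
            "params": self.params,
            "fixed": self.fixed,
            "baseline": {
                "OB_0": self.baseline.OB_0,
                "OC_0": self.baseline.OC_0,
                "B_0": self.baseline.B_0,
            },
            "LS": self.LS,
            "AIC": self.AIC,
            "per_variable_SS": self.per_variable_SS,
            "r_squared": self.r_squared,
            "n_residuals_below_one": {
                k: list(v) for k, v in self.n_residuals_below_one.items()
            },
            "converged": self.converged,
            "n_evals": self.n_evals,
            "seed": self.seed,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "se": self.se,
            "meta": self.meta,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)

    @classmethod
    def from_dict(cls, payload: dict) -> "FitResult":
        return cls(
            workflow=payload["workflow"],
            params=dict(payload["params"]),
            fixed=dict(payload["fixed"]),
            baseline=HomeostaticBaseline(**payload["baseline"]),
            LS=payload["LS"],
            AIC=payload["AIC"],
            per_variable_SS=dict(payload["per_variable_SS"]),
            r_squared=dict(payload["r_squared"]),
            n_residuals_below_one={
                k: tuple(v) for k, v in payload["n_residuals_below_one"].items()
            },
            converged=payload["converged"],
            n_evals=payload["n_evals"],
            seed=payload["seed"],
            bounds={k: tuple(v) for k, v in payload["bounds"].items()},
            se=payload.get("se"),
            meta=dict(payload.get("meta", {})),
        )

    def cell_parameters(self) -> InitialModelParameters:
        """Rebuild the full constant-rate parameter set (closures applied)."""
        merged = {**self.fixed, **self.params}
        return InitialModelParameters.with_closures(
            self.baseline,
            delta_OB=merged["delta_OB"],
            gamma_OB=merged["gamma_OB"],
            T_anab=merged["T_anab"],
            Inhib_OC=merged["Inhib_OC"],
            T_antiCatab=merged["T_antiCatab"],
            T_Catab=merged["T_Catab"],
            R_OC=merged["R_OC"],
            delta_B=merged.get("delta_B", 0.0),
            Pi_B=merged.get("Pi_B", None if "delta_B" in merged else 0.0),
        )


@dataclass
class BootstrapResult:
    """Per-parameter bootstrap standard errors (None when unavailable)."""

    se: dict[str, float] | None
    n_boot: int
    n_failures: int
    seed: int
    draws: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Frozen-cell bone integrator


class _FrozenCells:
    """Closed-form OB/OC trajectories on a fine grid, reused across objective
    evaluations of every bone-stage fit."""

    def __init__(
        self,
        cell_params: InitialModelParameters,
        baseline: HomeostaticBaseline,
        t_max: float,
        dt: float = _BONE_GRID_DT,
    ):
        n = int(round(t_max / dt)) + 1
        self.grid = np.linspace(0.0, t_max, n)
        self.dt = self.grid[1] - self.grid[0]
        self.OB, self.OC = cell_trajectories(cell_params, baseline, self.grid)
        self.baseline = baseline
        self.params = cell_params

    def bone(self, resorption_rate: np.ndarray, formation_rate: np.ndarray) -> np.ndarray:
        """Integrate dB/dt = -r(t)·OC(t)·B + f(t)·OB(t) exactly per step.

        ``resorption_rate`` and ``formation_rate`` are per-cell rates on the
        grid; within each step the loss/source coefficients are frozen at
        their midpoint values and the linear ODE is advanced in closed form.
        """
        a = resorption_rate * self.OC
        b = formation_rate * self.OB
        am = 0.5 * (a[:-1] + a[1:])
        bm = 0.5 * (b[:-1] + b[1:])
        dt = self.dt
        B = np.empty(self.grid.size)
        B[0] = self.baseline.B_0
        value = B[0]
        for i in range(am.size):
            ai = am[i]
            if ai > 1e-12:
                decay = math.exp(-ai * dt)
                value = value * decay + (bm[i] / ai) * (1.0 - decay)
            else:
                value = value + (bm[i] - ai * value) * dt
            B[i + 1] = value
        return B

    def bone_at(self, times, resorption_rate, formation_rate) -> np.ndarray:
        B = self.bone(resorption_rate, formation_rate)
        return np.interp(np.asarray(times, dtype=float), self.grid, B)


def _cells_from(cell_fit, baseline=None) -> tuple[InitialModelParameters, HomeostaticBaseline]:
    if isinstance(cell_fit, FitResult):
        return cell_fit.cell_parameters(), cell_fit.baseline
    if isinstance(cell_fit, InitialModelParameters):
        if baseline is None:
            raise ValueError("baseline required when passing raw parameters as the cell fit")
        return cell_fit, baseline
    raise TypeError(f"unsupported cell fit of type {type(cell_fit)!r}")


def _diagnostics(preds: dict[str, np.ndarray], data: TimeSeriesDataset,
                 variables: Sequence[str]):
    r2, counts = {}, {}
    for var in variables:
        try:
            r2[var] = gof.r_squared(preds, data, var)
        except gof.FlatDataError:
            r2[var] = float("nan")
        counts[var] = gof.count_residuals_below_one(preds, data, var)
    return r2, counts


def _build_result(
    *, workflow, params, fixed, baseline, outcome, data, variables,
    evaluator, bounds, seed, meta=None,
) -> FitResult:
    preds = evaluator(outcome.x)
    LS, per_variable = objective_LS(lambda _: preds, None, data, variables)
    r2, counts = _diagnostics(preds, data, variables)
    return FitResult(
        workflow=workflow,
        params=params,
        fixed=fixed,
        baseline=baseline,
        LS=LS,
        AIC=aic(len(params), LS),
        per_variable_SS=per_variable,
        r_squared=r2,
        n_residuals_below_one=counts,
        converged=outcome.converged,
        n_evals=outcome.n_evals,
        seed=seed,
        bounds=bounds,
        meta=meta or {},
    )


# ---------------------------------------------------------------------------
# Workflow 0: cell dynamics


CELL_FREE_NAMES = ("gamma_OB", "T_anab", "Inhib_OC", "T_antiCatab", "R_OC")


def _cell_start_heuristic(data: TimeSeriesDataset, baseline: HomeostaticBaseline,
                          delta_OB: float) -> np.ndarray:
    """Data-driven starting point for the five free cell parameters."""
    t = data.times
    ob = data.mean("OB")
    oc = data.mean("OC")
    i_peak = int(np.argmax(ob))
    t_peak = max(float(t[i_peak]), 1.0)
    growth = math.log(max(ob[i_peak] / baseline.OB_0, 1.001)) / t_peak
    gamma0 = growth + delta_OB
    t_anab0 = min(t_peak, float(t[-1]))
    i_min = int(np.argmin(oc))
    t_min = max(float(t[i_min]), 1.0)
    drop = -math.log(max(oc[i_min] / baseline.OC_0, 1e-6)) / t_min
    inhib0 = max(0.5 * drop, 0.05)
    t_anti0 = max(float(t[i_min]), 0.5)
    # recovery slope after the minimum approximates the replenishment rate
    later = oc[i_min:]
    t_later = t[i_min:]
    if later.size >= 2 and later[-1] > later[0]:
        r0 = (later[-1] - later[0]) / (t_later[-1] - t_later[0])
        r0 = max(r0, 0.01 * baseline.OC_0)
    else:
        r0 = 0.2 * baseline.OC_0
    return np.array([gamma0, t_anab0, inhib0, t_anti0, r0])


def calibrate_cell_dynamics(
    data: TimeSeriesDataset,
    *,
    delta_OB: float = TABLE_DELTA_OB,
    T_Catab: float = TABLE_T_CATAB,
    baseline: HomeostaticBaseline | None = None,
    start: Mapping[str, float] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    n_restarts: int = 5,
    max_evals: int | None = None,
) -> FitResult:
    """Stage 1: fit osteoblast and osteoclast dynamics (bone excluded).

    Free parameters: ``gamma_OB, T_anab, Inhib_OC, T_antiCatab, R_OC``.
    ``delta_OB`` is fixed from literature and ``T_Catab`` imposed; the source
    and clearance closures are applied at every candidate point.
    """
    if "OB" not in data.variables or "OC" not in data.variables:
        raise CalibrationError("cell calibration needs OB and OC variables in the data")
    if baseline is None:
        baseline = data.baseline()
    t_end = float(data.times[-1])
    limits = {
        "gamma_OB": (0.0, 10.0),
        "T_anab": (0.0, t_end),
        "Inhib_OC": (0.0, 20.0),
        "T_antiCatab": (0.0, t_end),
        "R_OC": (0.0, 20.0 * baseline.OC_0),
    }
    if bounds:
        limits.update(bounds)
    vec_bounds = [limits[name] for name in CELL_FREE_NAMES]

    if start is None:
        x0 = _cell_start_heuristic(data, baseline, delta_OB)
    else:
        x0 = np.array([start[name] for name in CELL_FREE_NAMES], dtype=float)

    def build(x: np.ndarray) -> InitialModelParameters:
        gamma, t_anab, inhib, t_anti, r_oc = np.maximum(x, 0.0)
        return InitialModelParameters.with_closures(
            baseline,
            delta_OB=delta_OB, gamma_OB=gamma, T_anab=t_anab,
            Inhib_OC=inhib, T_antiCatab=t_anti, T_Catab=T_Catab,
            R_OC=r_oc, delta_B=0.0, Pi_B=0.0,
        )

    def evaluator(x: np.ndarray) -> dict[str, np.ndarray]:
        OB, OC = cell_trajectories(build(x), baseline, data.times)
        return {"OB": OB, "OC": OC}

    def objective(x: np.ndarray) -> float:
        LS, _ = objective_LS(evaluator, x, data, ("OB", "OC"))
        return LS + bound_penalty(x, vec_bounds)

    outcome = minimize(objective, x0, bounds=vec_bounds, seed=seed,
                       n_restarts=n_restarts, max_evals=max_evals)
    params = dict(zip(CELL_FREE_NAMES, (float(v) for v in outcome.x)))
    fixed = {"delta_OB": delta_OB, "T_Catab": T_Catab}
    meta: dict = {"warnings": []}
    for name in ("gamma_OB", "Inhib_OC"):
        upper = limits[name][1]
        if params[name] < 1e-4 * upper:
            meta["warnings"].append(
                f"{name} fitted at ~0: the corresponding injury phase is "
                "unidentifiable in these data"
            )
    return _build_result(
        workflow="cells", params=params, fixed=fixed, baseline=baseline,
        outcome=outcome, data=data, variables=("OB", "OC"),
        evaluator=evaluator, bounds=limits, seed=seed, meta=meta,
    )


# ---------------------------------------------------------------------------
# Workflow helpers for the bone stages


def _frozen(cell_fit, data, baseline, dt=_BONE_GRID_DT) -> _FrozenCells:
    cell_params, base = _cells_from(cell_fit, baseline)
    return _FrozenCells(cell_params, base, float(data.times[-1]), dt=dt)


def _bone_outcome_stub(n_evals: int = 1, converged: bool = True) -> OptimizeOutcome:
    return OptimizeOutcome(x=np.empty(0), fun=float("nan"), n_evals=n_evals,
                           converged=converged, seed=0, n_restarts=0)


# ---------------------------------------------------------------------------
# Workflow 1: closure-constrained constant-rate scan


def scan_constant_rates(
    data: TimeSeriesDataset,
    cell_fit,
    rate_range: tuple[float, float] = PUBLISHED_RESORPTION_RANGE,
    n_samples: int = 25,
    *,
    baseline: HomeostaticBaseline | None = None,
) -> list[FitResult]:
    """Sample constant resorption rates on a log-uniform grid; the formation
    rate is set by the homeostasis closure in every sample so predictions
    eventually return to baseline bone volume.  Results are sorted by R²
    (best first)."""
    lo, hi = rate_range
    if not (0 < lo < hi):
        raise ValueError("rate_range must be positive and increasing")
    frozen = _frozen(cell_fit, data, baseline)
    base = frozen.baseline
    grid = np.logspace(math.log10(lo), math.log10(hi), n_samples)
    ones = np.ones_like(frozen.grid)
    results = []
    for delta_B in grid:
        Pi_B = delta_B * base.OC_0 * base.B_0 / base.OB_0
        preds = {"B": frozen.bone_at(data.times, delta_B * ones, Pi_B * ones)}
        LS, per_variable = objective_LS(lambda _: preds, None, data, ("B",))
        r2, counts = _diagnostics(preds, data, ("B",))
        results.append(
            FitResult(
                workflow="scan",
                params={"delta_B": float(delta_B)},
                fixed={**frozen.params.as_dict(), "Pi_B": float(Pi_B)},
                baseline=base,
                LS=LS,
                AIC=aic(1, LS),
                per_variable_SS=per_variable,
                r_squared=r2,
                n_residuals_below_one=counts,
                converged=True,
                n_evals=1,
                seed=0,
                bounds={"delta_B": rate_range},
                meta={"rate_grid_size": n_samples},
            )
        )
    results.sort(key=lambda fr: -fr.r_squared["B"])
    return results


# ---------------------------------------------------------------------------
# Workflow 2: free constant rates


def fit_free_constant_rates(
    data: TimeSeriesDataset,
    cell_fit,
    *,
    baseline: HomeostaticBaseline | None = None,
    rate_bounds: tuple[float, float] = PUBLISHED_RESORPTION_RANGE,
    formation_bounds: tuple[float, float] = (1e-10, 1e-3),
    seed: int = 0,
    n_restarts: int = 5,
    max_evals: int | None = None,
) -> FitResult:
    """Jointly optimize constant (delta_B, Pi_B) without the closure
    constraint; the terminal bone deficit ``B(T_end)/B_0 - 1`` is reported in
    ``meta`` since the fit is not forced to return to baseline."""
    frozen = _frozen(cell_fit, data, baseline)
    base = frozen.baseline
    ones = np.ones_like(frozen.grid)
    log_bounds = [tuple(math.log10(v) for v in rate_bounds),
                  tuple(math.log10(v) for v in formation_bounds)]
    mid = 10.0 ** (0.5 * (log_bounds[0][0] + log_bounds[0][1]))
    closure_start = min(max(mid * base.OC_0 * base.B_0 / base.OB_0,
                            formation_bounds[0]), formation_bounds[1])
    x0 = np.array([math.log10(mid), math.log10(closure_start)])

    def evaluator(x: np.ndarray) -> dict[str, np.ndarray]:
        delta_B, Pi_B = 10.0 ** x
        return {"B": frozen.bone_at(data.times, delta_B * ones, Pi_B * ones)}

    def objective(x: np.ndarray) -> float:
        LS, _ = objective_LS(evaluator, x, data, ("B",))
        return LS + bound_penalty(x, log_bounds)

    outcome = minimize(objective, x0, bounds=log_bounds, seed=seed,
                       n_restarts=n_restarts, max_evals=max_evals, jitter=0.05)
    delta_B, Pi_B = (float(v) for v in 10.0 ** outcome.x)
    params = {"delta_B": delta_B, "Pi_B": Pi_B}
    B_end = float(frozen.bone_at([data.times[-1]], delta_B * ones, Pi_B * ones)[0])
    result = _build_result(
        workflow="free_rates", params=params, fixed=frozen.params.as_dict(),
        baseline=base, outcome=outcome, data=data, variables=("B",),
        evaluator=evaluator, bounds={"delta_B": rate_bounds, "Pi_B": formation_bounds},
        seed=seed,
        meta={"terminal_bone_deficit": B_end / base.B_0 - 1.0},
    )
    return result


# ---------------------------------------------------------------------------
# Workflow 3: myeloid modulation


def fit_modulation(
    data: TimeSeriesDataset,
    cell_fit,
    pro_driver,
    anti_driver,
    *,
    baseline: HomeostaticBaseline | None = None,
    activity_range: tuple[float, float] = PUBLISHED_RESORPTION_RANGE,
    formation_activity_range: tuple[float, float] | None = None,
    alpha_bounds: tuple[float, float] = (0.0, 1e3),
    beta_bounds: tuple[float, float] = (0.0, 1e3),
    start: Mapping[str, float] | None = None,
    seed: int = 0,
    n_restarts: int = 5,
    max_evals: int | None = None,
) -> FitResult:
    """Fit (delta_B, alpha, beta) of the myeloid-modulated bone equation.

    ``Pi_B`` is pinned by the homeostasis closure at every candidate
    ``delta_B``.  A penalty keeps the modulated resorption activity
    ``delta_B * (1 + alpha * P(t))`` inside the published ``activity_range``
    for all t (and optionally the formation activity inside
    ``formation_activity_range``)."""
    frozen = _frozen(cell_fit, data, baseline)
    base = frozen.baseline
    P = np.asarray(pro_driver(frozen.grid), dtype=float)
    A = np.asarray(anti_driver(frozen.grid), dtype=float)
    lo, hi = activity_range

    if start is None:
        start = {"delta_B": math.sqrt(lo * hi), "alpha": 1.0, "beta": 1.0}
    x0 = np.array([math.log10(start["delta_B"]), start["alpha"], start["beta"]])
    vec_bounds = [
        (math.log10(lo), math.log10(hi)),
        alpha_bounds,
        beta_bounds,
    ]

    def rates(x: np.ndarray):
        delta_B = 10.0 ** x[0]
        alpha = max(x[1], 0.0)
        beta = max(x[2], 0.0)
        Pi_B = delta_B * base.OC_0 * base.B_0 / base.OB_0
        res = delta_B * (1.0 + alpha * P)
        form = Pi_B * (1.0 + beta * A)
        return delta_B, alpha, beta, Pi_B, res, form

    def evaluator(x: np.ndarray) -> dict[str, np.ndarray]:
        *_ , res, form = rates(x)
        return {"B": frozen.bone_at(data.times, res, form)}

    def activity_penalty(x: np.ndarray) -> float:
        *_, res, form = rates(x)
        width = hi - lo
        excess = max(0.0, float(res.max()) - hi) + max(0.0, lo - float(res.min()))
        total = (excess / width) ** 2
        if formation_activity_range is not None:
            flo, fhi = formation_activity_range
            fw = fhi - flo
            fex = max(0.0, float(form.max()) - fhi) + max(0.0, flo - float(form.min()))
            total += (fex / fw) ** 2
        return 1e6 * total

    def objective(x: np.ndarray) -> float:
        LS, _ = objective_LS(evaluator, x, data, ("B",))
        return LS + bound_penalty(x, vec_bounds) + activity_penalty(x)

    outcome = minimize(objective, x0, bounds=vec_bounds, seed=seed,
                       n_restarts=n_restarts, max_evals=max_evals)
    delta_B, alpha, beta, Pi_B, res, form = rates(outcome.x)
    params = {"delta_B": float(delta_B), "alpha": float(alpha), "beta": float(beta)}
    meta = {
        "Pi_B": float(Pi_B),
        "activity_range": list(activity_range),
        "resorption_activity_min": float(res.min()),
        "resorption_activity_max": float(res.max()),
        "formation_activity_min": float(form.min()),
        "formation_activity_max": float(form.max()),
        "drivers": {
            "pro": getattr(pro_driver, "to_records", lambda: None)(),
            "anti": getattr(anti_driver, "to_records", lambda: None)(),
        },
    }
    result = _build_result(
        workflow="modulation", params=params,
        fixed={**frozen.params.as_dict(), "Pi_B": float(Pi_B)},
        baseline=base, outcome=outcome, data=data, variables=("B",),
        evaluator=evaluator,
        bounds={"delta_B": activity_range, "alpha": alpha_bounds, "beta": beta_bounds},
        seed=seed, meta=meta,
    )
    return result


# ---------------------------------------------------------------------------
# Workflow 4: piecewise-linear time-varying rate


def fit_piecewise_rate(
    data: TimeSeriesDataset,
    cell_fit,
    which: str = "resorption",
    *,
    baseline: HomeostaticBaseline | None = None,
    n_segments: int = 8,
    rate_bounds: tuple[float, float] = (0.0, PUBLISHED_RESORPTION_RANGE[1]),
    slope_bounds: tuple[float, float] | None = None,
    fixed_other_rate: float | None = None,
    seed: int = 0,
    n_restarts: int = 5,
    max_evals: int | None = None,
) -> FitResult:
    """Fit a piecewise-linear per-cell rate (breakpoints on a uniform grid).

    Free parameters are the initial rate and one slope per segment; slopes
    may be positive or negative but the rate itself is penalized outside
    ``rate_bounds``.  The complementary constant rate defaults to the
    homeostasis closure anchored at the fitted initial rate, so the
    pre-injury state is a fixed point of every candidate model.  Multi-start
    runs use seeded random initial slopes.
    """
    if which not in ("resorption", "formation"):
        raise ValueError("which must be 'resorption' or 'formation'")
    frozen = _frozen(cell_fit, data, baseline)
    base = frozen.baseline
    t_end = float(data.times[-1])
    t_breaks = tuple(np.linspace(0.0, t_end, n_segments + 1))
    lo, hi = rate_bounds
    rate_scale = hi if math.isfinite(hi) and hi > 0 else 1e-5
    if slope_bounds is None:
        slope_bounds = (-rate_scale, rate_scale)  # per day
    closure_ratio = base.OC_0 * base.B_0 / base.OB_0

    x0 = np.concatenate([[0.2 * rate_scale], np.zeros(n_segments)])
    vec_bounds = [(max(lo, 1e-12 * rate_scale), hi)] + [slope_bounds] * n_segments

    def build(x: np.ndarray) -> PiecewiseRateFunction:
        return PiecewiseRateFunction(
            t_breaks=t_breaks, rate_0=max(float(x[0]), 0.0),
            slopes=tuple(float(s) for s in x[1:]),
            lower_bound=lo, upper_bound=hi,
        )

    def rate_arrays(x: np.ndarray):
        fn = build(x)
        varying = fn(frozen.grid)
        if which == "resorption":
            form = fixed_other_rate if fixed_other_rate is not None else fn.rate_0 * closure_ratio
            return varying, np.full_like(frozen.grid, form), fn
        res = fixed_other_rate if fixed_other_rate is not None else fn.rate_0 / closure_ratio
        return np.full_like(frozen.grid, res), varying, fn

    def evaluator(x: np.ndarray) -> dict[str, np.ndarray]:
        res, form, _ = rate_arrays(x)
        return {"B": frozen.bone_at(data.times, res, form)}

    def objective(x: np.ndarray) -> float:
        LS, _ = objective_LS(evaluator, x, data, ("B",))
        fn = build(x)
        width = hi - lo if math.isfinite(hi) else rate_scale
        rate_penalty = 1e6 * (fn.bound_violation() / width) ** 2
        return LS + bound_penalty(x, vec_bounds) + rate_penalty

    # Multi-start over randomized initial slopes (first start: flat rate).
    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(0, n_restarts - 1)):
        slopes = rng.uniform(-0.2, 0.2, n_segments) * rate_scale
        rate0 = rng.uniform(0.05, 0.5) * rate_scale
        starts.append(np.concatenate([[rate0], slopes]))
    best = None
    total_evals = 0
    run_values = []
    for k, s in enumerate(starts):
        outcome = minimize(objective, s, bounds=vec_bounds, seed=seed + k,
                           n_restarts=1, max_evals=max_evals)
        total_evals += outcome.n_evals
        run_values.append(outcome.fun)
        if best is None or outcome.fun < best.fun:
            best = outcome
    assert best is not None
    best.n_evals = total_evals

    res, form, fn = rate_arrays(best.x)
    if fn.bound_violation() > 1e-3 * rate_scale:
        warnings.warn("fitted piecewise rate violates its hard bounds", stacklevel=2)
    params = {"rate_0": float(best.x[0])}
    params.update({f"slope_{k + 1}": float(s) for k, s in enumerate(best.x[1:])})
    meta = {
        "which": which,
        "t_breaks": list(t_breaks),
        "rate_bounds": list(rate_bounds),
        "slope_bounds": list(slope_bounds),
        "fixed_other_rate": float(form[0]) if which == "resorption" else float(res[0]),
        "restart_objectives": run_values,
    }
    result = _build_result(
        workflow="piecewise", params=params, fixed=frozen.params.as_dict(),
        baseline=base, outcome=best, data=data, variables=("B",),
        evaluator=evaluator,
        bounds={"rate_0": rate_bounds, "slopes": slope_bounds},
        seed=seed, meta=meta,
    )
    return result


def piecewise_from_fit(fit: FitResult) -> PiecewiseRateFunction:
    """Reconstruct the fitted piecewise rate function from a FitResult."""
    if fit.workflow != "piecewise":
        raise ValueError("fit is not a piecewise-rate fit")
    n = len(fit.meta["t_breaks"]) - 1
    slopes = tuple(fit.params[f"slope_{k + 1}"] for k in range(n))
    lo, hi = fit.meta["rate_bounds"]
    return PiecewiseRateFunction(
        t_breaks=tuple(fit.meta["t_breaks"]), rate_0=fit.params["rate_0"],
        slopes=slopes, lower_bound=lo, upper_bound=hi,
    )


# ---------------------------------------------------------------------------
# Predictions and bootstrap


def predictions_from_fit(
    fit: FitResult,
    data: TimeSeriesDataset,
    *,
    pro_driver=None,
    anti_driver=None,
) -> dict[str, np.ndarray]:
    """Re-evaluate a fit's model predictions on the dataset's time points."""
    if fit.workflow == "cells":
        OB, OC = cell_trajectories(fit.cell_parameters(), fit.baseline, data.times)
        return {"OB": OB, "OC": OC}
    frozen = _FrozenCells(fit.cell_parameters(), fit.baseline, float(data.times[-1]))
    ones = np.ones_like(frozen.grid)
    if fit.workflow in ("scan", "free_rates"):
        delta_B = fit.params["delta_B"]
        Pi_B = fit.params.get("Pi_B", fit.fixed.get("Pi_B"))
        return {"B": frozen.bone_at(data.times, delta_B * ones, Pi_B * ones)}
    if fit.workflow == "modulation":
        if pro_driver is None or anti_driver is None:
            raise ValueError("modulation predictions need the driver curves")
        P = np.asarray(pro_driver(frozen.grid), dtype=float)
        A = np.asarray(anti_driver(frozen.grid), dtype=float)
        res = fit.params["delta_B"] * (1.0 + fit.params["alpha"] * P)
        form = fit.meta["Pi_B"] * (1.0 + fit.params["beta"] * A)
        return {"B": frozen.bone_at(data.times, res, form)}
    if fit.workflow == "piecewise":
        fn = piecewise_from_fit(fit)
        varying = fn(frozen.grid)
        other = fit.meta["fixed_other_rate"]
        if fit.meta["which"] == "resorption":
            return {"B": frozen.bone_at(data.times, varying, other * ones)}
        return {"B": frozen.bone_at(data.times, other * ones, varying)}
    raise ValueError(f"unknown workflow {fit.workflow!r}")


def bootstrap_se(
    workflow: Callable[..., FitResult],
    data: TimeSeriesDataset,
    n_boot: int = 50,
    seed: int = 0,
    max_failure_frac: float = 0.2,
) -> BootstrapResult:
    """Replicate-resampling bootstrap standard errors for any workflow.

    ``workflow(dataset)`` must return a :class:`FitResult`.  Replicates are
    resampled with replacement independently at every (variable, time point),
    means and σ recomputed, and the workflow refitted; the SE of each
    parameter is the standard deviation over refits.  With ``n_boot = 0`` the
    SEs are reported as unavailable (``se is None``), never as zero.  More
    than ``max_failure_frac`` refit failures also invalidates the SEs.
    """
    if n_boot == 0:
        return BootstrapResult(se=None, n_boot=0, n_failures=0, seed=seed)
    rng = np.random.default_rng(seed)
    draws: list[dict[str, float]] = []
    failures = 0
    for _ in range(n_boot):
        resampled = data.resample(rng)
        try:
            draws.append(workflow(resampled).params)
        except Exception:
            failures += 1
    if failures > max_failure_frac * n_boot or not draws:
        return BootstrapResult(se=None, n_boot=n_boot, n_failures=failures, seed=seed)
    frame = pd.DataFrame(draws)
    se = {name: float(frame[name].std(ddof=1)) for name in frame.columns}
    return BootstrapResult(se=se, n_boot=n_boot, n_failures=failures, seed=seed,
                           draws=frame)
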