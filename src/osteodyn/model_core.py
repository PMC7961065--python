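"""Core ODE models of trabecular bone injury repair.

Three coupled state variables are tracked: osteoblast abundance ``OB`` (cells
per reference marrow volume), osteoclast abundance ``OC`` (same units), and
bone volume ``B`` (mm^3, or a BV/TV fraction if the configuration uses one
consistently).  The injury response is modeled with sharp indicator windows:

* osteoblasts expand at rate ``gamma_OB`` during the anabolic window
  ``[0, T_anab]`` on top of a homeostatic source/clearance pair;
* osteoclasts are suppressed at rate ``Inhib_OC`` until ``T_antiCatab`` and
  replenished at rate ``R_OC`` from ``T_Catab`` onward, with homeostatic
  clearance active at all times;
* bone is resorbed at a per-cell, per-volume rate ``delta_B`` and formed at a
  per-cell rate ``Pi_B``.

Homeostasis closures pin the free source terms so that the pre-injury state
``(OB_0, OC_0, B_0)`` is an exact fixed point: ``H_OB = delta_OB * OB_0``,
``delta_OC_clear = R_OC / OC_0`` and (when the formation rate is constrained)
``Pi_B = delta_B * OC_0 * B_0 / OB_0``.

Two model extensions are supported: a myeloid-modulated variant where imposed
pro-/anti-inflammatory driver curves scale the resorption and formation rates
multiplicatively, and a piecewise-linear variant where either per-cell rate is
an explicit function of time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "StateVector",
    "HomeostaticBaseline",
    "InitialModelParameters",
    "ExpandedModelParameters",
    "PiecewiseRateFunction",
    "Trajectory",
    "SimulationError",
    "RateBoundError",
    "closure_source_ob",
    "closure_clearance_oc",
    "closure_formation_rate",
    "initial_rhs",
    "expanded_rhs",
    "piecewise_rhs",
    "evaluate_piecewise",
    "simulate",
    "cell_trajectories",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class SimulationError(RuntimeError):
    """Raised when the ODE integrator fails; carries the parameter snapshot."""


class RateBoundError(ValueError):
    """Raised when a piecewise rate is evaluated outside its hard bounds."""


def _require_nonnegative(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class StateVector:
    """Instantaneous (OB, OC, B) levels."""

    OB: float
    OC: float
    B: float

    def as_array(self) -> np.ndarray:
        return np.array([self.OB, self.OC, self.B], dtype=float)


@dataclass(frozen=True)
class HomeostaticBaseline:
    """Pre-injury steady state used both as initial condition and in closures."""

    OB_0: float
    OC_0: float
    B_0: float

    def __post_init__(self) -> None:
        for name in ("OB_0", "OC_0", "B_0"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"baseline {name} must be finite and > 0, got {value!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.OB_0, self.OC_0, self.B_0], dtype=float)


def closure_source_ob(delta_OB: float, baseline: HomeostaticBaseline) -> float:
    """Homeostatic osteoblast source ``H_OB = delta_OB * OB_0``."""
    _require_nonnegative(delta_OB=delta_OB)
    return delta_OB * baseline.OB_0


def closure_clearance_oc(R_OC: float, baseline: HomeostaticBaseline) -> float:
    """Homeostatic osteoclast clearance ``delta_OC_clear = R_OC / OC_0``."""
    _require_nonnegative(R_OC=R_OC)
    return R_OC / baseline.OC_0


def closure_formation_rate(delta_B: float, baseline: HomeostaticBaseline) -> float:
    """Per-cell formation rate ``Pi_B = delta_B * OC_0 * B_0 / OB_0``.

    Guarantees ``dB/dt = 0`` at the homeostatic state, so every resorption
    rate sampled in the closure-constrained workflow eventually restores bone
    to baseline.
    """
    _require_nonnegative(delta_B=delta_B)
    return delta_B * baseline.OC_0 * baseline.B_0 / baseline.OB_0


@dataclass(frozen=True)
class InitialModelParameters:
    """All rate constants and switch times of the constant-rate model.

    Units: rates in day^-1 unless stated; ``H_OB`` and ``R_OC`` in cells/day;
    ``delta_B`` in cell^-1 day^-1 (per bone-volume unit); ``Pi_B`` in
    mm^3 cell^-1 day^-1; switch times in days.
    """

    delta_OB: float
    H_OB: float
    gamma_OB: float
    T_anab: float
    Inhib_OC: float
    T_antiCatab: float
    T_Catab: float
    R_OC: float
    delta_OC_clear: float
    delta_B: float
    Pi_B: float

    def __post_init__(self) -> None:
        _require_nonnegative(
            delta_OB=self.delta_OB, H_OB=self.H_OB, gamma_OB=self.gamma_OB,
            T_anab=self.T_anab, Inhib_OC=self.Inhib_OC,
            T_antiCatab=self.T_antiCatab, T_Catab=self.T_Catab,
            R_OC=self.R_OC, delta_OC_clear=self.delta_OC_clear,
            delta_B=self.delta_B, Pi_B=self.Pi_B,
        )

    @classmethod
    def with_closures(
        cls,
        baseline: HomeostaticBaseline,
        *,
        delta_OB: float,
        gamma_OB: float,
        T_anab: float,
        Inhib_OC: float,
        T_antiCatab: float,
        T_Catab: float,
        R_OC: float,
        delta_B: float,
        Pi_B: float | None = None,
    ) -> "InitialModelParameters":
        """Build a parameter set with the homeostasis closures applied.

        ``Pi_B`` defaults to the formation closure; pass an explicit value to
        decouple formation from resorption (the free-rate workflow).
        """
        return cls(
            delta_OB=delta_OB,
            H_OB=closure_source_ob(delta_OB, baseline),
            gamma_OB=gamma_OB,
            T_anab=T_anab,
            Inhib_OC=Inhib_OC,
            T_antiCatab=T_antiCatab,
            T_Catab=T_Catab,
            R_OC=R_OC,
            delta_OC_clear=closure_clearance_oc(R_OC, baseline),
            delta_B=delta_B,
            Pi_B=closure_formation_rate(delta_B, baseline) if Pi_B is None else Pi_B,
        )

    def replace(self, **changes: float) -> "InitialModelParameters":
        return replace(self, **changes)

    def switch_times(self) -> tuple[float, ...]:
        return (self.T_anab, self.T_antiCatab, self.T_Catab)

    def as_dict(self) -> dict[str, float]:
        return {
            "delta_OB": self.delta_OB, "H_OB": self.H_OB,
            "gamma_OB": self.gamma_OB, "T_anab": self.T_anab,
            "Inhib_OC": self.Inhib_OC, "T_antiCatab": self.T_antiCatab,
            "T_Catab": self.T_Catab, "R_OC": self.R_OC,
            "delta_OC_clear": self.delta_OC_clear,
            "delta_B": self.delta_B, "Pi_B": self.Pi_B,
        }


@dataclass(frozen=True)
class ExpandedModelParameters:
    """Constant-rate parameters plus myeloid modulation of the bone equation.

    ``pro_driver`` and ``anti_driver`` are callables of time returning the
    excess fold change of the pro-inflammatory (monocyte+macrophage) and
    anti-inflammatory macrophage populations over homeostasis; both must be
    0 at homeostasis so the model reduces exactly to the base model when the
    drivers vanish or ``alpha = beta = 0``.
    """

    base: InitialModelParameters
    alpha: float
    beta: float
    pro_driver: Callable[[float], float]
    anti_driver: Callable[[float], float]

    def __post_init__(self) -> None:
        _require_nonnegative(alpha=self.alpha, beta=self.beta)


@dataclass(frozen=True)
class PiecewiseRateFunction:
    """Continuous piecewise-linear per-cell activity rate with hard bounds.

    The rate starts at ``rate_0`` at ``t_breaks[0]`` and follows one slope per
    segment.  Outside the covered interval the rate is held constant at the
    nearest node value.  Bounds are *not* applied silently on evaluation: the
    calibration penalty inspects :meth:`bound_violation`, and ``evaluate`` can
    be asked to raise on out-of-bound values.
    """

    t_breaks: tuple[float, ...]
    rate_0: float
    slopes: tuple[float, ...]
    lower_bound: float = 0.0
    upper_bound: float = math.inf

    def __post_init__(self) -> None:
        breaks = np.asarray(self.t_breaks, dtype=float)
        if breaks.size == 0:
            raise ValueError("t_breaks must contain at least one breakpoint")
        if breaks.size > 1 and not np.all(np.diff(breaks) > 0):
            raise ValueError("t_breaks must be strictly increasing")
        if len(self.slopes) != breaks.size - 1:
            raise ValueError(
                f"need len(t_breaks) - 1 = {breaks.size - 1} slopes, got {len(self.slopes)}"
            )
        if self.lower_bound > self.upper_bound:
            raise ValueError("lower_bound must not exceed upper_bound")
        object.__setattr__(self, "t_breaks", tuple(float(t) for t in breaks))
        object.__setattr__(self, "slopes", tuple(float(s) for s in self.slopes))

    @property
    def node_values(self) -> np.ndarray:
        """Rate at each breakpoint (piecewise-linear extrema live at nodes)."""
        breaks = np.asarray(self.t_breaks)
        if breaks.size == 1:
            return np.array([self.rate_0])
        increments = np.asarray(self.slopes) * np.diff(breaks)
        return np.concatenate([[self.rate_0], self.rate_0 + np.cumsum(increments)])

    def __call__(self, t):
        return np.interp(t, self.t_breaks, self.node_values)

    def evaluate(self, t, *, check_bounds: bool = False):
        """Evaluate the rate; optionally raise on hard-bound violations."""
        value = self(t)
        if check_bounds:
            violation = self.bound_violation()
            if violation > 0:
                raise RateBoundError(
                    f"piecewise rate leaves [{self.lower_bound}, {self.upper_bound}] "
                    f"by {violation:.3g}"
                )
        return value

    def bound_violation(self) -> float:
        """Largest excursion of any node value beyond the hard bounds (0 if none)."""
        nodes = self.node_values
        low = max(0.0, self.lower_bound - float(nodes.min()))
        high = float(nodes.max()) - self.upper_bound
        return max(low, 0.0 if math.isinf(self.upper_bound) else max(high, 0.0))


def evaluate_piecewise(fn: PiecewiseRateFunction, t):
    """Module-level alias for :meth:`PiecewiseRateFunction.evaluate`."""
    return fn.evaluate(t)


@dataclass
class Trajectory:
    """Dense model output sampled on a user grid."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, 3): columns OB, OC, B
    meta: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)  # e.g. driver evaluations P, A

    @property
    def OB(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def OC(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def B(self) -> np.ndarray:
        return self.states[:, 2]

    def value(self, variable: str) -> np.ndarray:
        return {"OB": self.OB, "OC": self.OC, "B": self.B}[variable]

    def to_frame(self):
        import pandas as pd

        frame = pd.DataFrame(
            {"time_day": self.times, "OB": self.OB, "OC": self.OC, "B": self.B}
        )
        for key, values in self.extras.items():
            frame[key] = values
        return frame


# ---------------------------------------------------------------------------
# Right-hand sides


def initial_rhs(t: float, state, params: InitialModelParameters):
    """Constant-rate model derivatives at time ``t`` (days)."""
    OB, OC, B = state
    p = params
    dOB = p.H_OB - p.delta_OB * OB
    if 0.0 <= t <= p.T_anab:
        dOB += p.gamma_OB * OB
    dOC = -p.delta_OC_clear * OC
    if t <= p.T_antiCatab:
        dOC -= p.Inhib_OC * OC
    if t >= p.T_Catab:
        dOC += p.R_OC
    dB = -p.delta_B * OC * B + p.Pi_B * OB
    return (dOB, dOC, dB)


def expanded_rhs(t: float, state, params: ExpandedModelParameters):
    """Myeloid-modulated derivatives: drivers scale the bone-equation rates."""
    OB, OC, B = state
    base = params.base
    dOB, dOC, _ = initial_rhs(t, state, base)
    P = float(params.pro_driver(t))
    A = float(params.anti_driver(t))
    dB = (
        -base.delta_B * (1.0 + params.alpha * P) * OC * B
        + base.Pi_B * (1.0 + params.beta * A) * OB
    )
    return (dOB, dOC, dB)


def piecewise_rhs(
    t: float,
    state,
    params: InitialModelParameters,
    resorption_fn: PiecewiseRateFunction | None = None,
    formation_fn: PiecewiseRateFunction | None = None,
):
    """Derivatives with time-varying per-cell bone rates.

    Cell dynamics follow ``params`` unchanged (in the staged workflow they are
    frozen from the prior cell fit); the bone equation uses the piecewise
    rate(s) in place of the constant ``delta_B`` / ``Pi_B``.
    """
    if resorption_fn is None and formation_fn is None:
        raise ValueError("provide at least one piecewise rate function")
    OB, OC, B = state
    dOB, dOC, _ = initial_rhs(t, state, params)
    res = float(resorption_fn(t)) if resorption_fn is not None else params.delta_B
    form = float(formation_fn(t)) if formation_fn is not None else params.Pi_B
    dB = -res * OC * B + form * OB
    return (dOB, dOC, dB)


# ---------------------------------------------------------------------------
# Integration


def _switch_points(
    params: InitialModelParameters,
    t_max: float,
    resorption_fn: PiecewiseRateFunction | None,
    formation_fn: PiecewiseRateFunction | None,
    extra: Sequence[float] = (),
) -> np.ndarray:
    points = set()
    for t in params.switch_times():
        if 0.0 < t < t_max:
            points.add(float(t))
    for fn in (resorption_fn, formation_fn):
        if fn is not None:
            points.update(t for t in fn.t_breaks if 0.0 < t < t_max)
    points.update(t for t in extra if 0.0 < t < t_max)
    return np.array(sorted(points))


def simulate(
    params: InitialModelParameters | ExpandedModelParameters,
    baseline: HomeostaticBaseline,
    t_grid,
    *,
    resorption_fn: PiecewiseRateFunction | None = None,
    formation_fn: PiecewiseRateFunction | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate a model variant from the homeostatic initial condition.

    Uses adaptive explicit Runge-Kutta (RK45) restarted at every indicator
    switch time and piecewise breakpoint so discontinuities never straddle a
    solver step silently.  ``t_grid`` must start at 0; the initial condition
    is ``(OB_0, OC_0, B_0)``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2:
        raise ValueError("t_grid must be a 1-D array with at least two points")
    if t_grid[0] != 0.0:
        raise ValueError("t_grid must start at 0 (baseline defines the initial condition)")
    if not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be strictly increasing")

    if isinstance(params, ExpandedModelParameters):
        base = params.base
        variant = "expanded"

        def rhs(t, y):
            return expanded_rhs(t, y, params)

        onset_times = []
        for driver in (params.pro_driver, params.anti_driver):
            pulses = getattr(driver, "pulses", ())
            onset_times.extend(p.onset for p in pulses)
    elif resorption_fn is not None or formation_fn is not None:
        base = params
        variant = "piecewise"

        def rhs(t, y):
            return piecewise_rhs(t, y, params, resorption_fn, formation_fn)

        onset_times = []
    else:
        base = params
        variant = "initial"

        def rhs(t, y):
            return initial_rhs(t, y, params)

        onset_times = []

    t_max = float(t_grid[-1])
    switches = _switch_points(base, t_max, resorption_fn, formation_fn, onset_times)
    edges = np.concatenate([[0.0], switches, [t_max]])

    y = baseline.as_array()
    times_out = [0.0]
    states_out = [y.copy()]
    for a, b in zip(edges[:-1], edges[1:]):
        interior = t_grid[(t_grid > a) & (t_grid < b)]
        t_eval = np.concatenate([interior, [b]])
        sol = solve_ivp(
            rhs, (a, b), y, method="RK45", t_eval=t_eval, rtol=rtol, atol=atol
        )
        if not sol.success:
            raise SimulationError(
                f"integration failed on [{a}, {b}]: {sol.message}; params={base.as_dict()}"
            )
        y = sol.y[:, -1].copy()
        keep = sol.t < b if b not in t_grid else np.ones(sol.t.size, dtype=bool)
        times_out.extend(sol.t[keep])
        states_out.extend(sol.y[:, keep].T)

    times = np.array(times_out)
    states = np.array(states_out)
    # Keep only requested grid points (segment ends were always integrated to).
    mask = np.isin(times, t_grid)
    times, states = times[mask], states[mask]
    if times.size != t_grid.size:  # pragma: no cover - defensive
        raise SimulationError("solver output does not cover the requested grid")

    # Structurally all variables stay >= 0; clamp integrator-level undershoot.
    floor = -(100.0 * atol + 1e-9 * float(np.max(baseline.as_array())))
    if states.min() < floor:
        raise SimulationError(
            f"negative state {states.min():.3g} exceeds solver tolerance; "
            f"params={base.as_dict()}"
        )
    states = np.maximum(states, 0.0)

    traj = Trajectory(
        times=times,
        states=states,
        meta={
            "variant": variant,
            "rtol": rtol,
            "atol": atol,
            "params": base.as_dict(),
            "baseline": {"OB_0": baseline.OB_0, "OC_0": baseline.OC_0, "B_0": baseline.B_0},
        },
    )
    if variant == "expanded":
        traj.extras["P"] = np.array([float(params.pro_driver(t)) for t in times])
        traj.extras["A"] = np.array([float(params.anti_driver(t)) for t in times])
    return traj


# ---------------------------------------------------------------------------
# Closed-form cell subsystem


def _linear_step(y0: float, c: float, s: float, dt):
    """Solve ``y' = s + c*y`` for time ``dt`` from ``y0`` (c may be 0)."""
    dt = np.asarray(dt, dtype=float)
    if c == 0.0:
        return y0 + s * dt
    return (y0 + s / c) * np.exp(c * dt) - s / c


def cell_trajectories(
    params: InitialModelParameters, baseline: HomeostaticBaseline, t
) -> tuple[np.ndarray, np.ndarray]:
    """Exact OB(t), OC(t) of the cell subsystem (piecewise-exponential).

    Both cell equations are linear with piecewise-constant coefficients, so
    the solution is available in closed form.  Used as the fast frozen-cell
    path in the staged bone fits and as an independent cross-check of
    :func:`simulate`.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("cell trajectories are defined for t >= 0")
    p = params

    def piecewise_linear_solution(switches_coeffs, y0):
        # switches_coeffs: list of (start_time, c, s) with start times ascending.
        out = np.empty_like(t)
        y_start = y0
        for k, (a, c, s) in enumerate(switches_coeffs):
            b = switches_coeffs[k + 1][0] if k + 1 < len(switches_coeffs) else math.inf
            mask = (t >= a) & (t < b) if not math.isinf(b) else t >= a
            out[mask] = _linear_step(y_start, c, s, t[mask] - a)
            if not math.isinf(b):
                y_start = float(_linear_step(y_start, c, s, b - a))
        return out

    # Osteoblasts: expansion window [0, T_anab], then pure source/clearance.
    ob_segments = [(0.0, p.gamma_OB - p.delta_OB, p.H_OB)]
    if p.T_anab > 0:
        ob_segments.append((p.T_anab, -p.delta_OB, p.H_OB))
    else:
        ob_segments = [(0.0, -p.delta_OB, p.H_OB)]
    OB = piecewise_linear_solution(ob_segments, baseline.OB_0)

    # Osteoclasts: switches at T_antiCatab (inhibition off) and T_Catab (source on).
    oc_switch_times = sorted({0.0, p.T_antiCatab, p.T_Catab})
    oc_segments = []
    for a in oc_switch_times:
        inhib_on = a < p.T_antiCatab  # inhibition window is t <= T_antiCatab
        source_on = a >= p.T_Catab
        c = -p.delta_OC_clear - (p.Inhib_OC if inhib_on else 0.0)
        s = p.R_OC if source_on else 0.0
        oc_segments.append((a, c, s))
    OC = piecewise_linear_solution(oc_segments, baseline.OC_0)

    return OB, OC
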