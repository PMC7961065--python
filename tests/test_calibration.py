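"""Objective, penalty, simplex search, AIC and the four fitting workflows."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteodyn import calibration as cal
from osteodyn import synthetic_data as sd
from osteodyn.calibration import (
    FitResult,
    TimeSeriesDataset,
    aic,
    bootstrap_se,
    bound_penalty,
    minimize,
    objective_LS,
    penalized_objective,
)
from osteodyn.model_core import cell_trajectories

from conftest import CELL_TRUTH


def random_dataset(rng, n_vars=3, n_reps=4):
    times = np.array([0.0, 1.0, 2.0, 3.0, 7.0, 14.0])
    values = {
        f"v{j}": rng.uniform(1.0, 10.0, (times.size, n_reps)) for j in range(n_vars)
    }
    return TimeSeriesDataset.from_arrays(times, values)


class TestDataset:
    def test_sigma_has_positive_floor_for_noiseless_replicates(self):
        times = np.array([0.0, 1.0, 2.0])
        data = TimeSeriesDataset.from_arrays(times, {"OB": np.full((3, 5), 10.0)})
        assert np.all(data.sigma("OB") == pytest.approx(0.05 * 10.0))

    def test_requires_time_zero(self):
        with pytest.raises(ValueError, match="time 0"):
            TimeSeriesDataset.from_arrays(np.array([1.0, 2.0]), {"OB": np.ones((2, 2))})

    def test_rejects_negative_values(self):
        import pandas as pd

        frame = pd.DataFrame(
            {"variable": ["OB"], "time_day": [0.0], "replicate": [1], "value": [-1.0]}
        )
        with pytest.raises(ValueError, match="negative"):
            TimeSeriesDataset(frame)

    def test_resample_is_deterministic_per_generator_state(self):
        data = random_dataset(np.random.default_rng(0))
        a = data.resample(np.random.default_rng(5)).to_long()
        b = data.resample(np.random.default_rng(5)).to_long()
        assert a.equals(b)


class TestObjective:
    def test_perfect_predictions_give_zero(self):
        data = random_dataset(np.random.default_rng(1))
        preds = {v: data.mean(v) for v in data.variables}
        LS, per = objective_LS(lambda _: preds, None, data)
        assert LS == 0.0
        assert all(v == 0.0 for v in per.values())

    def test_max_of_inner_sums(self):
        times = np.array([0.0, 1.0])
        data = TimeSeriesDataset.from_arrays(
            times, {"a": np.full((2, 2), 1.0), "b": np.full((2, 2), 1.0)}
        )
        sigma_a, sigma_b = data.sigma("a"), data.sigma("b")
        preds = {
            # inner sums: a -> 3.0, b -> 7.5 by construction
            "a": data.mean("a") + sigma_a * np.sqrt([1.0, 2.0]),
            "b": data.mean("b") + sigma_b * np.sqrt([3.5, 4.0]),
        }
        LS, per = objective_LS(lambda _: preds, None, data)
        assert per["a"] == pytest.approx(3.0)
        assert per["b"] == pytest.approx(7.5)
        assert LS == pytest.approx(7.5)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(2)
        data = random_dataset(rng)
        preds = {v: data.mean(v) * rng.uniform(0.5, 1.5, data.times.size)
                 for v in data.variables}
        LS, per = objective_LS(lambda _: preds, None, data)
        # independent double-loop oracle
        worst = -np.inf
        for var in data.variables:
            total = 0.0
            means, sigmas = data.mean(var), data.sigma(var)
            for i in range(data.times.size):
                total += (preds[var][i] - means[i]) ** 2 / sigmas[i] ** 2
            assert per[var] == pytest.approx(total, rel=1e-12)
            worst = max(worst, total)
        assert LS == pytest.approx(worst, rel=1e-12)

    def test_invariant_under_variable_and_time_permutation(self):
        rng = np.random.default_rng(3)
        data = random_dataset(rng)
        preds = {v: data.mean(v) + rng.normal(size=data.times.size)
                 for v in data.variables}
        LS, _ = objective_LS(lambda _: preds, None, data)
        shuffled_vars = list(reversed(data.variables))
        LS_perm, _ = objective_LS(lambda _: preds, None, data, shuffled_vars)
        assert LS_perm == pytest.approx(LS, rel=1e-12)
        order = rng.permutation(data.times.size)
        # permuting time points permutes each inner sum identically
        for var in data.variables:
            resid = (preds[var] - data.mean(var)) / data.sigma(var)
            assert np.sum(resid[order] ** 2) == pytest.approx(np.sum(resid**2), rel=1e-12)

    def test_missing_prediction_is_an_error(self):
        data = random_dataset(np.random.default_rng(4))
        with pytest.raises(cal.CalibrationError):
            objective_LS(lambda _: {}, None, data)


class TestPenalty:
    BOUNDS = [(0.0, 1.0), (-2.0, 2.0)]

    def test_zero_inside_bounds(self):
        assert bound_penalty(np.array([0.5, 0.0]), self.BOUNDS) == 0.0
        assert bound_penalty(np.array([0.0, 2.0]), self.BOUNDS) == 0.0  # boundary

    def test_violation_strictly_increases_objective(self):
        objective = lambda x: float(np.sum(x**2))
        inside = penalized_objective(objective, [0.5, 0.0], self.BOUNDS)
        outside = penalized_objective(objective, [2.0, 0.0], self.BOUNDS)
        assert outside > objective(np.array([2.0, 0.0]))
        assert inside == objective(np.array([0.5, 0.0]))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(v1=st.floats(0.01, 10.0), v2=st.floats(0.01, 10.0))
    def test_penalty_monotone_in_violation(self, v1, v2):
        small, large = sorted([v1, v2])
        p_small = bound_penalty(np.array([1.0 + small, 0.0]), self.BOUNDS)
        p_large = bound_penalty(np.array([1.0 + large, 0.0]), self.BOUNDS)
        assert p_small <= p_large
        if large > small:
            assert p_large > p_small


class TestMinimize:
    def test_quadratic_bowl(self):
        outcome = minimize(lambda x: (x[0] - 3.0) ** 2 + (x[1] + 1.0) ** 2,
                           [0.1, 0.1], seed=0)
        assert outcome.x == pytest.approx([3.0, -1.0], abs=1e-4)
        assert outcome.converged

    def test_bit_identical_repeat(self):
        kwargs = dict(start=[0.1, 0.1], seed=11, n_restarts=4)
        a = minimize(lambda x: (x[0] - 3.0) ** 2 + (x[1] + 1.0) ** 2, **kwargs)
        b = minimize(lambda x: (x[0] - 3.0) ** 2 + (x[1] + 1.0) ** 2, **kwargs)
        assert np.array_equal(a.x, b.x)
        assert a.fun == b.fun and a.n_evals == b.n_evals

    def test_recovers_growth_rate_from_noiseless_cell_data(self, paper_truth):
        data = sd.generate_dataset(paper_truth, sd.StudyDesign(noise_cv=0.0, seed=9))
        baseline = data.baseline()
        truth_gamma = paper_truth.params.gamma_OB

        def evaluator(x):
            p = paper_truth.params.replace(gamma_OB=max(float(x[0]), 0.0))
            OB, _ = cell_trajectories(p, baseline, data.times)
            return {"OB": OB}

        outcome = minimize(
            lambda x: objective_LS(evaluator, x, data, ("OB",))[0], [0.4], seed=0
        )
        assert outcome.x[0] == pytest.approx(truth_gamma, rel=0.01)


class TestAic:
    def test_arithmetic(self):
        assert aic(3, 10.0) == 16.0
        assert aic(0, 0.0) == 0.0

    def test_fewer_parameters_win_at_equal_fit(self):
        assert aic(2, 5.0) < aic(3, 5.0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            aic(-1, 0.0)


class TestCellCalibration:
    def test_zero_noise_recovery(self, cell_fit_zero):
        for name, value in CELL_TRUTH.items():
            assert cell_fit_zero.params[name] == pytest.approx(value, rel=0.05), name
        assert cell_fit_zero.converged

    def test_result_identities(self, cell_fit_zero):
        assert cell_fit_zero.LS == max(cell_fit_zero.per_variable_SS.values())
        assert cell_fit_zero.AIC == aic(len(cell_fit_zero.params), cell_fit_zero.LS)

    def test_flat_data_flags_unidentifiable_phases(self):
        times = np.array([0.0, 1.0, 2.0, 3.0, 7.0, 14.0])
        data = TimeSeriesDataset.from_arrays(
            times,
            {"OB": np.full((6, 3), 500.0), "OC": np.full((6, 3), 2000.0)},
        )
        fit = cal.calibrate_cell_dynamics(data, seed=0, n_restarts=3)
        assert fit.params["gamma_OB"] == pytest.approx(0.0, abs=1e-3)
        assert fit.params["Inhib_OC"] == pytest.approx(0.0, abs=1e-2)
        assert fit.meta["warnings"]


class TestScan:
    def test_best_sample_is_nearest_grid_point_to_truth(
        self, data_initial_zero, cell_fit_initial, paper_truth_initial
    ):
        results = cal.scan_constant_rates(data_initial_zero, cell_fit_initial,
                                          n_samples=25)
        grid = np.array([fr.params["delta_B"] for fr in results])
        truth = paper_truth_initial.params.delta_B
        nearest = grid[np.argmin(np.abs(np.log(grid) - np.log(truth)))]
        assert results[0].params["delta_B"] == pytest.approx(nearest, rel=1e-12)

    def test_single_sample_at_truth_is_perfect(
        self, data_initial_zero, cell_fit_initial, paper_truth_initial
    ):
        truth = paper_truth_initial.params.delta_B
        results = cal.scan_constant_rates(
            data_initial_zero, cell_fit_initial, rate_range=(truth, truth * 1.0000001),
            n_samples=1,
        )
        assert results[0].r_squared["B"] == pytest.approx(1.0, abs=1e-6)

    def test_every_sample_satisfies_the_closure_identity(
        self, data_initial_zero, cell_fit_initial
    ):
        results = cal.scan_constant_rates(data_initial_zero, cell_fit_initial,
                                          n_samples=9)
        for fr in results:
            base = fr.baseline
            assert fr.fixed["Pi_B"] * base.OB_0 == pytest.approx(
                fr.params["delta_B"] * base.OC_0 * base.B_0, rel=1e-12
            )


class TestFreeRates:
    def test_zero_noise_recovery(self, data_initial_zero, cell_fit_initial,
                                 paper_truth_initial):
        fit = cal.fit_free_constant_rates(data_initial_zero, cell_fit_initial, seed=0)
        assert fit.params["delta_B"] == pytest.approx(
            paper_truth_initial.params.delta_B, rel=0.05
        )
        assert fit.params["Pi_B"] == pytest.approx(
            paper_truth_initial.params.Pi_B, rel=0.05
        )

    def test_closure_consistent_truth_recovers_closure(
        self, data_initial_zero, cell_fit_initial
    ):
        fit = cal.fit_free_constant_rates(data_initial_zero, cell_fit_initial, seed=0)
        base = fit.baseline
        closure = fit.params["delta_B"] * base.OC_0 * base.B_0 / base.OB_0
        assert fit.params["Pi_B"] == pytest.approx(closure, rel=0.05)

    def test_resorption_overshoot_reports_negative_deficit(self, paper_truth_initial):
        # formation far below the closure value: bone cannot rebuild and the
        # trajectory ends below baseline, the hallmark of the unconstrained fit
        base = paper_truth_initial.baseline
        params = paper_truth_initial.params.replace(
            Pi_B=0.005 * paper_truth_initial.params.Pi_B
        )
        truth = sd.GroundTruth(params=params, baseline=base, variant="initial",
                               drivers=paper_truth_initial.drivers)
        data = sd.generate_dataset(truth, sd.StudyDesign(noise_cv=0.0, seed=5))
        cell = cal.calibrate_cell_dynamics(data, seed=0)
        fit = cal.fit_free_constant_rates(data, cell, seed=0)
        assert fit.meta["terminal_bone_deficit"] < 0.0


class TestModulation:
    def test_zero_noise_recovery(self, mod_fit_zero, paper_truth):
        assert mod_fit_zero.params["delta_B"] == pytest.approx(
            paper_truth.params.delta_B, rel=0.05
        )
        assert mod_fit_zero.params["alpha"] == pytest.approx(paper_truth.alpha, rel=0.05)
        assert mod_fit_zero.params["beta"] == pytest.approx(paper_truth.beta, rel=0.05)

    def test_modulated_rate_stays_in_published_range(self, mod_fit_zero):
        lo, hi = cal.PUBLISHED_RESORPTION_RANGE
        assert mod_fit_zero.meta["resorption_activity_min"] >= lo
        assert mod_fit_zero.meta["resorption_activity_max"] <= hi

    def test_null_modulation_detected(self, paper_truth, data_zero, cell_fit_zero):
        null_truth = sd.GroundTruth(
            params=paper_truth.params, baseline=paper_truth.baseline,
            variant="expanded", alpha=0.0, beta=0.0, drivers=paper_truth.drivers,
        )
        data = sd.generate_dataset(null_truth, sd.StudyDesign(noise_cv=0.0, seed=4))
        fit = cal.fit_modulation(
            data, cell_fit_zero, paper_truth.pro_driver(), paper_truth.anti_driver(),
            seed=0,
        )
        assert fit.params["alpha"] <= 1e-3
        assert fit.params["beta"] <= 1e-3


class TestPiecewise:
    def test_two_wave_rate_recovered(self, piecewise_fit, piecewise_truth):
        fitted = cal.piecewise_from_fit(piecewise_fit)
        grid = np.linspace(0.0, 14.0, 561)
        r = np.corrcoef(fitted(grid), piecewise_truth.resorption_fn(grid))[0, 1]
        assert r >= 0.9

    def test_restarts_agree(self, piecewise_fit):
        values = np.array(piecewise_fit.meta["restart_objectives"])
        best = values.min()
        # 10% agreement with an absolute floor for near-zero noiseless objectives
        assert np.all(values <= 1.1 * best + 1e-6)

    def test_fitted_rate_respects_bounds(self, piecewise_fit):
        fitted = cal.piecewise_from_fit(piecewise_fit)
        assert fitted.bound_violation() <= 1e-3 * 5e-5

    def test_constant_rate_truth_yields_flat_rate(self, paper_truth_initial):
        design = sd.StudyDesign(times=tuple(float(t) for t in range(15)),
                                noise_cv=0.0, seed=6)
        data = sd.generate_dataset(paper_truth_initial, design)
        cell = cal.calibrate_cell_dynamics(data, seed=0)
        fit = cal.fit_piecewise_rate(data, cell, n_segments=8, seed=0,
                                     n_restarts=2, max_evals=6000)
        nodes = cal.piecewise_from_fit(fit).node_values
        assert np.ptp(nodes) / nodes.mean() < 0.1


class TestBootstrap:
    def test_zero_noise_se_is_negligible(self, data_initial_zero, cell_fit_initial):
        boot = bootstrap_se(
            lambda d: cal.fit_free_constant_rates(d, cell_fit_initial, seed=0,
                                                  n_restarts=1),
            data_initial_zero, n_boot=3, seed=0,
        )
        fit = cal.fit_free_constant_rates(data_initial_zero, cell_fit_initial,
                                          seed=0, n_restarts=1)
        for name, se in boot.se.items():
            assert se < 1e-3 * abs(fit.params[name])

    def test_se_grows_with_noise(self, paper_truth_initial, cell_fit_initial):
        ses = {}
        for cv in (0.05, 0.20):
            data = sd.generate_dataset(
                paper_truth_initial, sd.StudyDesign(noise_cv=cv, seed=8)
            )
            boot = bootstrap_se(
                lambda d: cal.fit_free_constant_rates(d, cell_fit_initial, seed=0,
                                                      n_restarts=2),
                data, n_boot=12, seed=2,
            )
            ses[cv] = boot.se
        for name in ses[0.05]:
            assert ses[0.20][name] > ses[0.05][name]

    def test_zero_draws_reports_unavailable(self, data_initial_zero):
        boot = bootstrap_se(lambda d: None, data_initial_zero, n_boot=0, seed=0)
        assert boot.se is None


class TestFitResult:
    def test_json_round_trip(self, cell_fit_zero):
        payload = json.loads(cell_fit_zero.to_json())
        restored = FitResult.from_dict(payload)
        assert restored.params == cell_fit_zero.params
        assert restored.LS == cell_fit_zero.LS
        assert restored.baseline == cell_fit_zero.baseline

    def test_stored_identities_for_all_workflows(self, cell_fit_zero, mod_fit_zero,
                                                 piecewise_fit):
        for fit in (cell_fit_zero, mod_fit_zero, piecewise_fit):
            assert fit.LS == max(fit.per_variable_SS.values())
            assert fit.AIC == aic(len(fit.params), fit.LS)
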