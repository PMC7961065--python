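"""Shared fixtures: ground truths, synthetic datasets and staged fits.

The expensive staged fits are session-scoped so that unit tests and the
acceptance suite reuse the same computations.
"""

from __future__ import annotations

import numpy as np
import pytest

from osteodyn import calibration as cal
from osteodyn import synthetic_data as sd
from osteodyn.model_core import PiecewiseRateFunction

CELL_TRUTH = {
    "gamma_OB": 0.873,
    "T_anab": 6.6924,
    "Inhib_OC": 1.2186,
    "T_antiCatab": 2.0,
    "R_OC": 6774.8,
}


@pytest.fixture(scope="session")
def paper_truth():
    return sd.paper_like_truth("expanded")


@pytest.fixture(scope="session")
def paper_truth_initial():
    return sd.paper_like_truth("initial")


@pytest.fixture(scope="session")
def data_zero(paper_truth):
    """Noise-free dataset from the expanded-model fixture (study design)."""
    return sd.generate_dataset(paper_truth, sd.StudyDesign(noise_cv=0.0, seed=1))


@pytest.fixture(scope="session")
def data_noisy(paper_truth):
    """CV = 10%, n = 5 dataset from the expanded-model fixture."""
    return sd.generate_dataset(paper_truth, sd.StudyDesign(noise_cv=0.10, seed=7))


@pytest.fixture(scope="session")
def cell_fit_zero(data_zero):
    return cal.calibrate_cell_dynamics(data_zero, seed=0)


@pytest.fixture(scope="session")
def cell_fit_noisy(data_noisy):
    return cal.calibrate_cell_dynamics(data_noisy, seed=0)


@pytest.fixture(scope="session")
def mod_fit_zero(data_zero, cell_fit_zero, paper_truth):
    return cal.fit_modulation(
        data_zero, cell_fit_zero, paper_truth.pro_driver(), paper_truth.anti_driver(),
        seed=0,
    )


@pytest.fixture(scope="session")
def data_initial_zero(paper_truth_initial):
    """Noise-free dataset from the constant-rate fixture (published delta_B)."""
    return sd.generate_dataset(paper_truth_initial, sd.StudyDesign(noise_cv=0.0, seed=2))


@pytest.fixture(scope="session")
def cell_fit_initial(data_initial_zero):
    return cal.calibrate_cell_dynamics(data_initial_zero, seed=0)


@pytest.fixture(scope="session")
def piecewise_truth(paper_truth_initial):
    """Two-wave resorption rate: intense transient wave around days 1-2,
    milder persistent wave after day 3 (on the fit's uniform 8-segment grid
    so recovery against the generating truth is well-posed)."""
    base = paper_truth_initial.baseline
    t_breaks = tuple(np.linspace(0.0, 14.0, 9))
    nodes = np.array([5e-7, 7e-6, 1.2e-6, 3e-6, 2.6e-6, 2.2e-6, 1.6e-6, 1.0e-6, 6e-7])
    fn = PiecewiseRateFunction(
        t_breaks=t_breaks, rate_0=float(nodes[0]),
        slopes=tuple(np.diff(nodes) / np.diff(np.asarray(t_breaks))),
        lower_bound=0.0, upper_bound=5e-5,
    )
    params = paper_truth_initial.params.replace(
        Pi_B=fn.rate_0 * base.OC_0 * base.B_0 / base.OB_0
    )
    return sd.GroundTruth(
        params=params, baseline=base, variant="piecewise",
        drivers=paper_truth_initial.drivers, resorption_fn=fn,
    )


@pytest.fixture(scope="session")
def piecewise_data(piecewise_truth):
    # Daily sampling: a 9-parameter rate cannot be recovered from 5 bone points.
    design = sd.StudyDesign(times=tuple(float(t) for t in range(15)), noise_cv=0.0, seed=3)
    return sd.generate_dataset(piecewise_truth, design)


@pytest.fixture(scope="session")
def piecewise_cell_fit(piecewise_data):
    return cal.calibrate_cell_dynamics(piecewise_data, seed=0)


@pytest.fixture(scope="session")
def piecewise_fit(piecewise_data, piecewise_cell_fit):
    return cal.fit_piecewise_rate(
        piecewise_data, piecewise_cell_fit, n_segments=8, seed=0,
        n_restarts=5, max_evals=6000,
    )
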