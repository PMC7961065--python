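"""Readers, writers, configuration and the command-line interface.

Datasets travel as long-format CSV (``variable,time_day,replicate,value``);
fits and diagnostics as JSON; model configurations as YAML with ``model``,
``baseline``, ``solver`` and ``drivers`` sections.  Every file the package
writes carries a provenance comment block (tool version, seed, config hash)
so a run is reproducible from its config and seed alone.
"""

from __future__ import annotations

import hashlib
import json
import sys
import warnings
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import (
    ALL_VARIABLES,
    FitResult,
    TimeSeriesDataset,
    calibrate_cell_dynamics,
    fit_free_constant_rates,
    fit_modulation,
    fit_piecewise_rate,
    predictions_from_fit,
    scan_constant_rates,
)
from .goodness_of_fit import activity_from_fit, count_residuals_below_one, fold_range, r_squared
from .model_core import (
    ExpandedModelParameters,
    HomeostaticBaseline,
    InitialModelParameters,
    Trajectory,
    simulate,
)
from .myeloid_drivers import DriverCurve, combine_pro_driver
from .synthetic_data import GroundTruth, StudyDesign, generate_dataset, paper_like_truth

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_trajectory",
    "load_config",
    "save_config",
    "params_from_config",
    "drivers_from_config",
    "write_fit",
    "read_fit",
    "cli",
]

_DATASET_COLUMNS = ["variable", "time_day", "replicate", "value"]


def _metadata_block(seed=None, extra=None) -> str:
    payload = {"tool": f"osteodyn {__version__}"}
    if seed is not None:
        payload["seed"] = seed
    if extra:
        payload.update(extra)
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:12]
    payload["config_hash"] = digest
    return "".join(f"# {k}: {v}\n" for k, v in payload.items())


def read_dataset(path, *, allowed_variables=ALL_VARIABLES,
                 sigma_floor_frac: float = 0.05) -> TimeSeriesDataset:
    """Read and validate a long-format dataset CSV.

    Malformed rows are rejected with their line number; unknown variable
    labels are skipped with a warning; negative values and empty files are
    errors.
    """
    path = Path(path)
    frame = pd.read_csv(path, comment="#")
    if len(frame) == 0:
        raise ValueError(f"{path}: no data rows")
    missing = set(_DATASET_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    numeric = pd.to_numeric(frame["value"], errors="coerce")
    bad = frame.index[numeric.isna()]
    if len(bad):
        raise ValueError(f"{path}: malformed value at data row {int(bad[0]) + 2}")
    frame["value"] = numeric
    neg = frame.index[frame["value"] < 0]
    if len(neg):
        raise ValueError(f"{path}: negative value at data row {int(neg[0]) + 2}")
    if allowed_variables is not None:
        unknown = sorted(set(frame["variable"]) - set(allowed_variables))
        if unknown:
            warnings.warn(f"{path}: skipping unknown variables {unknown}", stacklevel=2)
            frame = frame[~frame["variable"].isin(unknown)]
        if len(frame) == 0:
            raise ValueError(f"{path}: no rows with known variable labels")
    return TimeSeriesDataset(frame[_DATASET_COLUMNS], sigma_floor_frac=sigma_floor_frac)


def write_dataset(data: TimeSeriesDataset, path, *, seed=None) -> None:
    path = Path(path)
    with open(path, "w") as handle:
        handle.write(_metadata_block(seed=seed, extra={"content": "dataset"}))
        data.to_long().to_csv(handle, index=False)


def write_trajectory(traj: Trajectory, path, *, seed=None) -> None:
    path = Path(path)
    with open(path, "w") as handle:
        handle.write(_metadata_block(seed=seed, extra={"content": "trajectory"}))
        traj.to_frame().to_csv(handle, index=False)


# ---------------------------------------------------------------------------
# Configuration


def load_config(path) -> dict:
    with open(path) as handle:
        config = yaml.safe_load(handle)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return config


def save_config(config: dict, path) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(config, handle, sort_keys=True)


def drivers_from_config(config: dict) -> dict[str, DriverCurve]:
    return {
        name: DriverCurve.from_records(records, name)
        for name, records in config.get("drivers", {}).items()
    }


def params_from_config(config: dict):
    """Build (params, baseline, solver options) from a config mapping.

    The ``model`` section holds the flat parameter fields; if ``alpha`` or
    ``beta`` are present together with a ``drivers`` section the expanded
    variant is built.
    """
    baseline = HomeostaticBaseline(**config["baseline"])
    model = dict(config["model"])
    alpha = model.pop("alpha", None)
    beta = model.pop("beta", None)
    if "H_OB" in model:  # fully explicit parameter set
        params = InitialModelParameters(**model)
    else:
        params = InitialModelParameters.with_closures(baseline, **model)
    solver = config.get("solver", {})
    if alpha is None and beta is None:
        return params, baseline, solver
    drivers = drivers_from_config(config)
    pro = combine_pro_driver(drivers["pro_mono"], drivers["pro_mac"])
    expanded = ExpandedModelParameters(
        base=params, alpha=alpha or 0.0, beta=beta or 0.0,
        pro_driver=pro, anti_driver=drivers["anti_mac"],
    )
    return expanded, baseline, solver


def config_from_truth(truth: GroundTruth) -> dict:
    payload = truth.to_dict()
    config = {
        "model": payload["params"],
        "baseline": payload["baseline"],
        "solver": {"rtol": 1e-8, "atol": 1e-10},
        "drivers": payload["drivers"],
    }
    if truth.variant == "expanded":
        config["model"]["alpha"] = truth.alpha
        config["model"]["beta"] = truth.beta
    return config


# ---------------------------------------------------------------------------
# Fit serialization


def write_fit(fit: FitResult, path) -> None:
    Path(path).write_text(fit.to_json() + "\n")


def read_fit(path) -> FitResult:
    return FitResult.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# CLI


@click.group(name="osteodyn")
@click.version_option(__version__)
def cli() -> None:
    """ODE modeling of trabecular bone injury repair."""


@cli.command()
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", type=click.Path(dir_okay=False), required=True)
@click.option("--truth-out", type=click.Path(dir_okay=False), default=None)
@click.option("--noise-cv", type=float, default=0.10, show_default=True)
@click.option("--replicates", type=int, default=5, show_default=True)
@click.option("--variant", type=click.Choice(["initial", "expanded"]), default="expanded")
def generate(seed, out, truth_out, noise_cv, replicates, variant):
    """Generate a synthetic study dataset from the packaged ground truth."""
    truth = paper_like_truth(variant)
    design = StudyDesign(noise_cv=noise_cv, n_replicates=replicates, seed=seed)
    data = generate_dataset(truth, design)
    write_dataset(data, out, seed=seed)
    if truth_out:
        Path(truth_out).write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n")
    click.echo(f"wrote {out}")


@cli.command("simulate")
@click.option("--config", "config_path", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(dir_okay=False), required=True)
@click.option("--t-max", type=float, default=14.0, show_default=True)
@click.option("--n-points", type=int, default=281, show_default=True)
def simulate_cmd(config_path, out, t_max, n_points):
    """Integrate the configured model and write the trajectory CSV."""
    params, baseline, solver = params_from_config(load_config(config_path))
    grid = np.linspace(0.0, t_max, n_points)
    traj = simulate(params, baseline, grid,
                    rtol=solver.get("rtol", 1e-8), atol=solver.get("atol", 1e-10))
    write_trajectory(traj, out)
    click.echo(f"wrote {out}")


@cli.command()
@click.option("--data", "data_path", type=click.Path(exists=True), required=True)
@click.option("--workflow", type=click.Choice(["cells", "free-rates", "modulation", "piecewise"]),
              required=True)
@click.option("--cell-fit", "cell_fit_path", type=click.Path(exists=True), default=None)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None,
              help="YAML with a drivers section (required for modulation).")
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--restarts", type=int, default=5, show_default=True)
@click.option("--out", type=click.Path(dir_okay=False), required=True)
def fit(data_path, workflow, cell_fit_path, config_path, seed, restarts, out):
    """Run one fitting workflow and write the FitResult JSON."""
    data = read_dataset(data_path)
    if workflow == "cells":
        result = calibrate_cell_dynamics(data, seed=seed, n_restarts=restarts)
    else:
        if cell_fit_path is None:
            raise click.UsageError(f"--cell-fit is required for workflow {workflow}")
        cell_fit = read_fit(cell_fit_path)
        if workflow == "free-rates":
            result = fit_free_constant_rates(data, cell_fit, seed=seed, n_restarts=restarts)
        elif workflow == "modulation":
            if config_path is None:
                raise click.UsageError("--config with a drivers section is required")
            drivers = drivers_from_config(load_config(config_path))
            pro = combine_pro_driver(drivers["pro_mono"], drivers["pro_mac"])
            result = fit_modulation(data, cell_fit, pro, drivers["anti_mac"],
                                    seed=seed, n_restarts=restarts)
        else:
            result = fit_piecewise_rate(data, cell_fit, seed=seed, n_restarts=restarts)
    write_fit(result, out)
    click.echo(f"wrote {out} (LS={result.LS:.4g}, AIC={result.AIC:.4g})")


@cli.command()
@click.option("--data", "data_path", type=click.Path(exists=True), required=True)
@click.option("--cell-fit", "cell_fit_path", type=click.Path(exists=True), required=True)
@click.option("--n-samples", type=int, default=25, show_default=True)
@click.option("--out", type=click.Path(dir_okay=False), required=True)
def scan(data_path, cell_fit_path, n_samples, out):
    """Scan closure-constrained constant resorption rates."""
    data = read_dataset(data_path)
    cell_fit = read_fit(cell_fit_path)
    results = scan_constant_rates(data, cell_fit, n_samples=n_samples)
    payload = [fr.to_dict() for fr in results]
    Path(out).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    best = results[0]
    click.echo(f"wrote {out} (best R^2={best.r_squared['B']:.4f} "
               f"at delta_B={best.params['delta_B']:.3e})")


@cli.command()
@click.option("--fit", "fit_path", type=click.Path(exists=True), required=True)
@click.option("--data", "data_path", type=click.Path(exists=True), required=True)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None,
              help="YAML with a drivers section (needed for modulation fits).")
@click.option("--out", type=click.Path(dir_okay=False), required=True)
def evaluate(fit_path, data_path, config_path, out):
    """Recompute diagnostics (R², #R<1, AIC, fold ranges) for a stored fit."""
    result = read_fit(fit_path)
    data = read_dataset(data_path)
    pro = anti = None
    if result.workflow == "modulation":
        records = result.meta.get("drivers", {})
        if config_path is not None:
            drivers = drivers_from_config(load_config(config_path))
            pro = combine_pro_driver(drivers["pro_mono"], drivers["pro_mac"])
            anti = drivers["anti_mac"]
        elif records.get("pro") and records.get("anti"):
            pro = DriverCurve.from_records(records["pro"], "pro_combined")
            anti = DriverCurve.from_records(records["anti"], "anti_mac")
        else:
            raise click.UsageError("modulation fit needs --config with drivers")
    preds = predictions_from_fit(result, data, pro_driver=pro, anti_driver=anti)
    diagnostics = {
        "workflow": result.workflow,
        "AIC": result.AIC,
        "LS": result.LS,
        "r_squared": {},
        "n_residuals_below_one": {},
        "convention": "post-baseline replicate means; strict |R| < 1",
    }
    for var in preds:
        if var not in data.variables:
            continue
        diagnostics["r_squared"][var] = r_squared(preds, data, var)
        diagnostics["n_residuals_below_one"][var] = list(
            count_residuals_below_one(preds, data, var)
        )
    if result.workflow in ("modulation", "piecewise", "scan", "free_rates"):
        try:
            res_tc, form_tc = activity_from_fit(result, pro, anti)
            diagnostics["fold_range"] = {
                "resorption": fold_range(res_tc),
                "formation": fold_range(form_tc),
            }
        except ValueError as err:
            diagnostics["fold_range"] = {"flagged": str(err)}
    Path(out).write_text(json.dumps(diagnostics, indent=2, sort_keys=True) + "\n")
    click.echo(f"wrote {out}")


def main(argv=None) -> int:
    try:
        cli.main(args=argv, standalone_mode=False)
        return 0
    except click.ClickException as err:
        err.show()
        return err.exit_code
    except SystemExit as err:  # --help / usage errors
        return int(err.code or 0)
    except Exception as err:  # pragma: no cover - defensive
        print(f"error: {err}", file=sys.stderr)
        return 1
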