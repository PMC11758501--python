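"""Bundled scenario fixtures: the five standard marginal-probability rows."""

from __future__ import annotations

from importlib import resources

import numpy as np
import yaml

from .scenarios import (
    CalibrationResult,
    CovariateSpec,
    DoseGrid,
    calibrate_truth,
)

__all__ = ["load_marginal_table", "standard_dose_grid", "build_truths"]


def load_marginal_table() -> dict:
    """Raw bundled scenario table (doses, reference dose, tau, rows)."""
    text = (
        resources.files("pmtdsim.data")
        .joinpath("marginal_scenarios.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


def standard_dose_grid() -> DoseGrid:
    tab = load_marginal_table()
    return DoseGrid(tuple(tab["doses"]), tab["reference_dose"])


def build_truths(
    gamma: tuple[float, ...] = (),
    covariate_spec: CovariateSpec | None = None,
    family: str = "logistic",
    scenarios: tuple[str, ...] | None = None,
) -> dict[str, CalibrationResult]:
    """Calibrated truths for the bundled scenarios, keyed by scenario name.

    With ``gamma`` non-empty, coefficients are re-solved so that the
    *marginal* probabilities still match the bundled rows.
    """
    tab = load_marginal_table()
    grid = DoseGrid(tuple(tab["doses"]), tab["reference_dose"])
    names = scenarios or tuple(tab["scenarios"])
    out: dict[str, CalibrationResult] = {}
    for nm in names:
        targets = np.asarray(tab["scenarios"][nm], dtype=float)
        out[nm] = calibrate_truth(
            targets,
            family=family,
            gamma=gamma,
            covariate_spec=covariate_spec,
            dose_grid=grid,
            tau=tab["tau"],
            name=nm,
        )
    return out
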