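"""Configuration loading and tabular readers/writers.

All formats are plain text: YAML configs, CSV tables, JSON sidecars.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import DesignSpec, TrialRecord
from .inference import FitSettings, TrialData
from .oc import OCResult
from .priors import BayesianLasso, FlatNormal, PriorSpec, SpikeSlab
from .scenarios import (
    CalibrationResult,
    Covariate,
    CovariateSpec,
    DoseGrid,
    ScenarioTruth,
    calibrate_truth,
)

__all__ = [
    "load_scenarios",
    "load_design",
    "config_hash",
    "write_trial_record",
    "read_trial_data",
    "write_trial_data",
    "write_oc_tables",
    "load_supplementary_coefficients",
]


def config_hash(obj) -> str:
    """Stable short hash of a config mapping, recorded in every output."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _covariate_spec(cfg: dict) -> CovariateSpec:
    descs = []
    for c in cfg.get("covariates", []) or []:
        kind = c["kind"]
        if kind in ("normal", "continuous"):
            descs.append(Covariate.normal(c.get("mean", 0.0), c.get("sd", 1.0)))
        elif kind in ("bernoulli", "binary"):
            descs.append(Covariate.bernoulli(c.get("prob", 0.5)))
        else:
            raise ValueError(f"unknown covariate kind {kind!r}")
    corr = cfg.get("correlation")
    return CovariateSpec(
        tuple(descs),
        tuple(tuple(row) for row in corr) if corr is not None else None,
    )


def load_scenarios(path: str | Path) -> dict[str, ScenarioTruth]:
    """Build scenario truths from a YAML file.

    Each scenario entry gives either explicit ``coefficients`` or target
    ``marginals`` to calibrate against (with ``gamma`` fixed).
    """
    cfg = yaml.safe_load(Path(path).read_text())
    grid = DoseGrid(tuple(cfg["doses"]), cfg["reference_dose"])
    tau = float(cfg.get("tau", 0.25))
    spec = _covariate_spec(cfg)
    out: dict[str, ScenarioTruth] = {}
    for sc in cfg["scenarios"]:
        name = str(sc["name"])
        family = sc.get("family", "logistic")
        gamma = tuple(sc.get("gamma", []) or [])
        if "coefficients" in sc:
            out[name] = ScenarioTruth(
                family, grid, tuple(sc["coefficients"]), gamma, spec, tau, name
            )
        elif "marginals" in sc:
            res = calibrate_truth(
                sc["marginals"], family=family, gamma=gamma,
                covariate_spec=spec, dose_grid=grid, tau=tau, name=name,
            )
            out[name] = res.truth
        else:
            raise ValueError(f"scenario {name}: coefficients or marginals required")
    return out


_PRIOR_TYPES = {
    "flat_normal": FlatNormal,
    "lasso": BayesianLasso,
    "spike_slab": SpikeSlab,
}


def _prior(cfg: dict | None) -> PriorSpec:
    cfg = cfg or {}
    kwargs = {}
    if "base_mean" in cfg:
        kwargs["base_mean"] = tuple(cfg["base_mean"])
    if "base_cov" in cfg:
        kwargs["base_cov"] = tuple(tuple(r) for r in cfg["base_cov"])
    cov_cfg = cfg.get("covariate")
    if cov_cfg:
        cov_cfg = dict(cov_cfg)
        cls = _PRIOR_TYPES[cov_cfg.pop("type")]
        kwargs["covariate"] = cls(**cov_cfg)
    return PriorSpec(**kwargs)


def load_design(path: str | Path) -> DesignSpec:
    """Build a design from a YAML file (dose/covariate indices 1-based)."""
    cfg = yaml.safe_load(Path(path).read_text())
    settings = FitSettings(**(cfg.get("settings") or {}))
    return DesignSpec(
        method=cfg["method"],
        prior=_prior(cfg.get("prior")),
        tau=float(cfg.get("tau", 0.25)),
        n_patients=int(cfg.get("n_patients", 30)),
        cohort_size=int(cfg.get("cohort_size", 3)),
        start_dose=int(cfg.get("start_dose", 1)) - 1,
        covariate_indices=tuple(
            int(i) - 1 for i in (cfg.get("covariate_indices") or [])
        ),
        cchange_thresholds=tuple(cfg.get("cchange_thresholds") or []),
        engine=cfg.get("engine", "auto"),
        settings=settings,
        no_skip=bool(cfg.get("no_skip", False)),
    )


def write_trial_data(data: TrialData, grid: DoseGrid, path: str | Path,
                     cohort: np.ndarray | None = None) -> None:
    df = pd.DataFrame({"patient_id": np.arange(1, data.n + 1)})
    if cohort is not None:
        df["cohort"] = np.asarray(cohort) + 1
    df["dose_index"] = data.dose_index + 1
    df["dose_mg"] = np.asarray(grid.doses)[data.dose_index]
    for j in range(data.p):
        df[f"x{j + 1}"] = data.covariates[:, j]
    df["dlt"] = data.outcome
    df.to_csv(path, index=False)


def read_trial_data(path: str | Path, grid: DoseGrid) -> TrialData:
    df = pd.read_csv(path)
    xcols = sorted(
        (c for c in df.columns if c.startswith("x") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    return TrialData(
        df["dose_index"].to_numpy() - 1,
        df[xcols].to_numpy() if xcols else np.empty((len(df), 0)),
        df["dlt"].to_numpy(),
    )


def write_trial_record(record: TrialRecord, grid: DoseGrid, out_dir: str | Path,
                       meta: dict | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_trial_data(record.data, grid, out / "patients.csv", record.cohort_of)
    sidecar = {
        "seed": record.seed,
        "final_covariate_indices": [i + 1 for i in record.final_covariate_indices],
        "flags": record.flags,
        "cohorts": [
            {
                "cohort": log.cohort + 1,
                "doses": (log.doses + 1).tolist(),
                "ratios": {str(k + 1): v for k, v in log.ratios.items()},
                "included_after": [i + 1 for i in log.included_after],
                "phat_reference": log.phat_reference.tolist(),
            }
            for log in record.cohorts
        ],
        "inclusion_history": (
            [list(h) for h in record.inclusion.history]
            if record.inclusion is not None
            else None
        ),
    }
    if meta:
        sidecar["meta"] = meta
    (out / "trial.json").write_text(json.dumps(sidecar, indent=2))


def write_oc_tables(result: OCResult, out_dir: str | Path,
                    meta: dict | None = None, label: str = "oc") -> None:
    """Wide table (per-scenario columns + summary) plus a long-format CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = result.per_scenario
    wide = {"model": label}
    for metric in ("mtd_add", "ov_add", "mtd_trial", "ov_trial"):
        for _, row in df.iterrows():
            wide[f"{metric}.{row['scenario']}"] = row[metric]
        wide[f"{metric}.mean"] = result.summary[metric]
    pd.DataFrame([wide]).to_csv(out / "oc_wide.csv", index=False)
    long = df.melt(id_vars=["scenario", "n_trials"], var_name="metric")
    long.to_csv(out / "oc_long.csv", index=False)
    manifest = {
        "n_sim": result.n_sim,
        "master_seed": result.master_seed,
        "n_failed": result.n_failed,
        "summary": result.summary,
    }
    if meta:
        manifest.update(meta)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_supplementary_coefficients(path: str | Path) -> pd.DataFrame:
    """Optional loader for externally supplied scenario coefficients.

    Expects a CSV with columns: scenario, alpha, beta, then gamma1..gammaP.
    """
    df = pd.read_csv(path)
    required = {"scenario", "alpha", "beta"}
    if not required.issubset(df.columns):
        raise ValueError(f"coefficient table must contain columns {sorted(required)}")
    return df
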