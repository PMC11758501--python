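"""Operating-characteristics engine.

Replicates trials per scenario, scores personalised-MTD allocation and
overdosing both during the trial and for a fresh post-trial cohort of
additional patients, and aggregates across scenarios: within-scenario
averages over trials are arithmetic; the cross-scenario summary uses the
geometric mean for correct-allocation metrics and the arithmetic mean for
overdosing metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DesignSpec, TrialRecord, run_trial
from .scenarios import CovariateSpec, ScenarioTruth, closest_dose_rows, true_pmtd_rows

__all__ = [
    "TrialMetrics",
    "OCResult",
    "gen_covariates",
    "evaluate_additional",
    "trial_metrics",
    "aggregate",
    "run_oc",
    "calibrate_hyperparameter",
]

MTD_METRICS = ("mtd_add", "mtd_trial")
OV_METRICS = ("ov_add", "ov_trial")


@dataclass(frozen=True)
class TrialMetrics:
    """Four per-trial percentages in [0, 100]."""

    mtd_trial: float
    ov_trial: float
    mtd_add: float
    ov_add: float

    def __post_init__(self) -> None:
        for name in ("mtd_trial", "ov_trial", "mtd_add", "ov_add"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} outside [0, 100]: {v}")


def gen_covariates(spec: CovariateSpec, n: int, seed: int) -> np.ndarray:
    """Draw an (n, p) covariate matrix reproducibly."""
    return spec.sample(n, np.random.default_rng(seed))


def evaluate_additional(
    truth: ScenarioTruth,
    record: TrialRecord,
    n_add: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """(mtd_add, ov_add) for ``n_add`` fresh patients scored with the
    trial's final working model."""
    if truth.p:
        X = gen_covariates(truth.covariate_spec, n_add, seed)
    else:
        X = np.empty((n_add, 0))
    cols = list(record.final_covariate_indices)
    post = record.final_posterior
    if post.n_covariates:
        rec = closest_dose_rows(post.prob_matrix(X[:, cols]), truth.tau)
    else:
        rec = np.full(
            n_add,
            closest_dose_rows(post.prob_curve()[None, :], truth.tau)[0],
        )
    pmtd = true_pmtd_rows(truth, X)
    return (
        100.0 * float(np.mean(rec == pmtd)),
        100.0 * float(np.mean(rec > pmtd)),
    )


def trial_metrics(truth: ScenarioTruth, record: TrialRecord) -> tuple[float, float]:
    """(mtd_trial, ov_trial) over the enrolled patients of one record."""
    pmtd = true_pmtd_rows(truth, record.data.covariates)
    assigned = record.allocations
    return (
        100.0 * float(np.mean(assigned == pmtd)),
        100.0 * float(np.mean(assigned > pmtd)),
    )


def geometric_mean(values: Sequence[float]) -> float:
    v = np.asarray(values, dtype=float)
    if np.any(v == 0):
        warnings.warn("geometric mean over values containing 0", RuntimeWarning)
        return 0.0
    return float(np.exp(np.mean(np.log(v))))


@dataclass
class OCResult:
    """Per-scenario operating characteristics plus the summary row."""

    per_scenario: pd.DataFrame
    summary: dict[str, float]
    n_sim: int
    master_seed: int | None = None
    n_failed: dict[str, int] = field(default_factory=dict)

    def scenario_values(self, metric: str) -> np.ndarray:
        return self.per_scenario[metric].to_numpy()


def aggregate(
    per_trial: Mapping[str, Sequence[TrialMetrics]],
    n_sim: int | None = None,
    master_seed: int | None = None,
    n_failed: Mapping[str, int] | None = None,
) -> OCResult:
    """Arithmetic within-scenario averaging over trials; geometric summary
    for MTD metrics and arithmetic summary for overdose metrics."""
    rows = []
    for name, metrics in per_trial.items():
        if not metrics:
            raise ValueError(f"scenario {name!r} has no trials")
        rows.append(
            {
                "scenario": name,
                "n_trials": len(metrics),
                **{
                    m: float(np.mean([getattr(t, m) for t in metrics]))
                    for m in MTD_METRICS + OV_METRICS
                },
            }
        )
    df = pd.DataFrame(rows)
    summary = {m: geometric_mean(df[m]) for m in MTD_METRICS}
    summary.update({m: float(df[m].mean()) for m in OV_METRICS})
    return OCResult(
        per_scenario=df,
        summary=summary,
        n_sim=n_sim or int(df["n_trials"].max()),
        master_seed=master_seed,
        n_failed=dict(n_failed or {}),
    )


def _trial_seed(master_seed: int, s_idx: int, t_idx: int) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=(s_idx, t_idx))
    return int(ss.generate_state(1)[0])


def run_oc(
    truths: Sequence[ScenarioTruth] | Mapping[str, ScenarioTruth],
    design: DesignSpec,
    n_sim: int,
    master_seed: int = 0,
    n_add: int = 100,
    n_jobs: int = 1,
) -> OCResult:
    """Full operating-characteristics table for one design.

    Per-trial seeds derive deterministically from ``master_seed`` and the
    (scenario, trial) index, so results are independent of execution order
    and worker count.  Individual trial failures are logged and counted,
    not silently dropped.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if isinstance(truths, Mapping):
        items = list(truths.items())
    else:
        items = [(t.name or f"scenario_{i + 1}", t) for i, t in enumerate(truths)]

    def one_trial(truth: ScenarioTruth, s_idx: int, t_idx: int) -> TrialMetrics:
        seed = _trial_seed(master_seed, s_idx, t_idx)
        record = run_trial(truth, design, seed)
        mtd_t, ov_t = trial_metrics(truth, record)
        mtd_a, ov_a = evaluate_additional(
            truth, record, n_add=n_add, seed=_trial_seed(master_seed, s_idx, t_idx + 10**6)
        )
        return TrialMetrics(mtd_t, ov_t, mtd_a, ov_a)

    per_trial: dict[str, list[TrialMetrics]] = {}
    n_failed: dict[str, int] = {}
    for s_idx, (name, truth) in enumerate(items):
        results: list[TrialMetrics] = []
        failed = 0
        if n_jobs > 1:
            from joblib import Parallel, delayed

            out = Parallel(n_jobs=n_jobs)(
                delayed(one_trial)(truth, s_idx, t) for t in range(n_sim)
            )
            results = list(out)
        else:
            for t in range(n_sim):
                try:
                    results.append(one_trial(truth, s_idx, t))
                except Exception as exc:  # noqa: BLE001 - count, don't drop run
                    failed += 1
                    warnings.warn(
                        f"trial {t} of scenario {name} failed: {exc}",
                        RuntimeWarning,
                    )
        if not results:
            raise RuntimeError(f"all trials failed for scenario {name}")
        per_trial[name] = results
        n_failed[name] = failed
    return aggregate(per_trial, n_sim=n_sim, master_seed=master_seed, n_failed=n_failed)


@dataclass
class CalibrationSurface:
    best_value: float
    surface: pd.DataFrame            # columns: value, case, mtd_add summary
    scores: pd.DataFrame             # columns: value, score (geo mean over cases)
    results: dict[tuple[float, str], OCResult]


def calibrate_hyperparameter(
    design_builder: Callable[[float, str], DesignSpec],
    grid: Sequence[float],
    truth_cases: Mapping[str, Sequence[ScenarioTruth] | Mapping[str, ScenarioTruth]],
    n_sim: int,
    master_seed: int = 0,
    n_add: int = 100,
    n_jobs: int = 1,
) -> CalibrationSurface:
    """Grid search of one design hyperparameter.

    The score of a grid value is the geometric mean, across the covariate
    cases, of the summary (cross-scenario geometric mean) of mtd_add.
    """
    if not len(grid):
        raise ValueError("grid must be non-empty")
    rows, score_rows = [], []
    results: dict[tuple[float, str], OCResult] = {}
    for value in grid:
        case_scores = []
        for case, truths in truth_cases.items():
            design = design_builder(value, case)
            res = run_oc(
                truths, design, n_sim, master_seed=master_seed,
                n_add=n_add, n_jobs=n_jobs,
            )
            results[(float(value), case)] = res
            rows.append(
                {"value": value, "case": case, "mtd_add": res.summary["mtd_add"]}
            )
            case_scores.append(res.summary["mtd_add"])
        score_rows.append({"value": value, "score": geometric_mean(case_scores)})
    scores = pd.DataFrame(score_rows)
    best = float(scores.loc[scores["score"].idxmax(), "value"])
    return CalibrationSurface(
        best_value=best,
        surface=pd.DataFrame(rows),
        scores=scores,
        results=results,
    )
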