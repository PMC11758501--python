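"""Dose-allocation rules, covariate-inclusion criterion and trial conduct.

Methods
-------
``blrm``
    covariate-free two-parameter model; one shared dose per cohort.
``blrmc``
    covariate-extended model with flat-normal coefficient priors; every
    patient is allocated to their estimated personalised MTD.
``lasso`` / ``spike_slab``
    same allocation rule with shrinkage / selection priors on the
    coefficients.
``cchange``
    starts covariate-free; after every cohort, for each candidate covariate
    the fraction of enrolled patients whose recommended dose differs
    between the current working model and the model augmented with that
    covariate is compared against a threshold.  Once included, a covariate
    stays included for the rest of the trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .inference import FitSettings, PosteriorEstimate, TrialData, fit_posterior
from .priors import BayesianLasso, FlatNormal, PriorSpec, SpikeSlab
from .scenarios import ScenarioTruth, closest_dose, closest_dose_rows

__all__ = [
    "DesignSpec",
    "InclusionState",
    "CohortLog",
    "TrialRecord",
    "select_dose",
    "allocate_cohort",
    "cchange_ratio",
    "update_inclusion",
    "run_trial",
]

METHODS = ("blrm", "blrmc", "lasso", "spike_slab", "cchange")


@dataclass(frozen=True)
class DesignSpec:
    """Configuration of one dose-finding design."""

    method: str
    prior: PriorSpec = field(default_factory=PriorSpec)
    tau: float = 0.25
    n_patients: int = 30
    cohort_size: int = 3
    start_dose: int = 0
    covariate_indices: tuple[int, ...] = ()
    cchange_thresholds: tuple[float, ...] = ()
    engine: str = "auto"
    settings: FitSettings = field(default_factory=FitSettings)
    no_skip: bool = False

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not 0 < self.tau < 1:
            raise ValueError("tau must be in (0,1)")
        if self.n_patients % self.cohort_size:
            raise ValueError("n_patients must be divisible by cohort_size")
        object.__setattr__(
            self, "covariate_indices", tuple(int(i) for i in self.covariate_indices)
        )
        object.__setattr__(
            self,
            "cchange_thresholds",
            tuple(float(t) for t in self.cchange_thresholds),
        )
        if self.method == "cchange":
            if len(self.cchange_thresholds) != len(self.covariate_indices):
                raise ValueError(
                    "one cchange threshold per candidate covariate required"
                )
        if self.method != "blrm" and self.method != "cchange":
            if self.prior.covariate is None and self.covariate_indices:
                raise ValueError("covariate model requires a covariate prior")

    @property
    def n_cohorts(self) -> int:
        return self.n_patients // self.cohort_size


@dataclass(frozen=True)
class InclusionState:
    """Monotone per-covariate inclusion flags with the cchange history."""

    included: tuple[bool, ...]
    history: tuple[tuple[float, ...], ...] = ()

    def active(self) -> tuple[int, ...]:
        return tuple(i for i, f in enumerate(self.included) if f)


def select_dose(p_hat: Sequence[float], tau: float) -> int:
    """Dose minimising |p_hat - tau|, ties broken to the highest dose."""
    return closest_dose(np.asarray(p_hat, dtype=float), tau)


def allocate_cohort(
    post: PosteriorEstimate,
    cohort_covariates: np.ndarray,
    tau: float,
    covariate_aware: bool,
) -> np.ndarray:
    """Dose index per cohort member.

    Covariate-unaware: one shared dose from the marginal posterior curve.
    Covariate-aware: per-patient dose from p_hat(d | x_i).
    """
    X = np.atleast_2d(np.asarray(cohort_covariates, dtype=float))
    n = X.shape[0]
    if not covariate_aware:
        return np.full(n, select_dose(post.prob_curve(), tau), dtype=int)
    return closest_dose_rows(post.prob_matrix(X), tau).astype(int)


def _recommendations(
    post: PosteriorEstimate, data: TrialData, cols: tuple[int, ...], tau: float
) -> np.ndarray:
    """Current recommended dose for every enrolled patient under one fit."""
    if post.n_covariates == 0:
        return np.full(data.n, select_dose(post.prob_curve(), tau), dtype=int)
    X = data.covariates[:, list(cols)]
    return closest_dose_rows(post.prob_matrix(X), tau).astype(int)


def cchange_ratio(
    data: TrialData,
    post_without: PosteriorEstimate,
    post_with: PosteriorEstimate,
    tau: float,
    cols_without: tuple[int, ...] = (),
    cols_with: tuple[int, ...] = (),
) -> float:
    """Fraction of enrolled patients whose recommended dose differs between
    the model without and with the candidate covariate."""
    if data.n == 0:
        raise ValueError("cchange ratio undefined with no patients")
    rec_wo = _recommendations(post_without, data, cols_without, tau)
    rec_w = _recommendations(post_with, data, cols_with, tau)
    return float(np.mean(rec_wo != rec_w))


def update_inclusion(
    state: InclusionState,
    ratios: Sequence[float],
    thresholds: Sequence[float],
) -> InclusionState:
    """Include covariate j iff R_j strictly exceeds its threshold; inclusion
    is permanent once reached."""
    ratios = tuple(float(r) for r in ratios)
    thresholds = tuple(float(t) for t in thresholds)
    if not len(ratios) == len(thresholds) == len(state.included):
        raise ValueError("ratios, thresholds and state must align")
    new = tuple(
        inc or (r > t) for inc, r, t in zip(state.included, ratios, thresholds)
    )
    return InclusionState(included=new, history=state.history + (ratios,))


@dataclass
class CohortLog:
    cohort: int
    doses: np.ndarray
    ratios: dict[int, float]
    included_after: tuple[int, ...]
    phat_reference: np.ndarray  # posterior curve at x = 0 after this cohort


@dataclass
class TrialRecord:
    """Full audit trail of one simulated trial."""

    data: TrialData                      # full covariate matrix as generated
    cohort_of: np.ndarray
    allocations: np.ndarray
    inclusion: InclusionState | None
    final_posterior: PosteriorEstimate
    final_covariate_indices: tuple[int, ...]
    cohorts: list[CohortLog]
    seed: int
    flags: list[str] = field(default_factory=list)


def _fit_seed(master: int, cohort: int, cols: tuple[int, ...]) -> np.random.SeedSequence:
    mask = sum(1 << c for c in cols)
    return np.random.SeedSequence(master, spawn_key=(3, cohort, mask))


def _model_kinds(truth: ScenarioTruth, cols: tuple[int, ...]) -> tuple[str, ...]:
    return tuple(truth.covariate_spec.kinds[c] for c in cols)


def _fit(
    truth: ScenarioTruth,
    design: DesignSpec,
    data: TrialData,
    cols: tuple[int, ...],
    cohort: int,
    seed: int,
    prior: PriorSpec | None = None,
) -> PosteriorEstimate:
    prior = prior or design.prior
    if not cols:
        prior = replace(prior, covariate=None)
    elif prior.covariate is None:
        # cchange candidate models default to the flat-normal coefficient prior
        prior = replace(prior, covariate=FlatNormal())
    return fit_posterior(
        prior,
        data.select_covariates(cols),
        truth.dose_grid,
        kinds=_model_kinds(truth, cols),
        engine=design.engine,
        settings=design.settings,
        seed=_fit_seed(seed, cohort, cols),
    )


def run_trial(truth: ScenarioTruth, design: DesignSpec, seed: int) -> TrialRecord:
    """Simulate one sequential trial under ``truth`` with ``design``.

    The covariate and outcome random streams depend only on (seed, cohort),
    never on the design, so trial paths of two designs under the same seed
    are comparable patient by patient.
    """
    p_truth = truth.p
    if design.method == "blrm":
        model_cols: tuple[int, ...] = ()
    else:
        model_cols = design.covariate_indices or tuple(range(p_truth))
    if any(c >= p_truth for c in model_cols):
        raise ValueError("covariate index outside the truth's covariates")

    is_cchange = design.method == "cchange"
    candidates = model_cols if is_cchange else ()
    inclusion = (
        InclusionState(included=(False,) * len(candidates)) if is_cchange else None
    )
    active: tuple[int, ...] = () if is_cchange else model_cols

    data = TrialData.empty(p_truth)
    allocations = np.empty(design.n_patients, dtype=int)
    cohort_of = np.empty(design.n_patients, dtype=int)
    logs: list[CohortLog] = []
    flags: list[str] = []
    post: PosteriorEstimate | None = None
    n_c = design.cohort_size

    for c in range(design.n_cohorts):
        cov_rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(1, c))
        )
        X_c = (
            truth.covariate_spec.sample(n_c, cov_rng)
            if p_truth
            else np.empty((n_c, 0))
        )
        if c == 0:
            doses = np.full(n_c, design.start_dose, dtype=int)
        else:
            doses = allocate_cohort(
                post,
                X_c[:, list(active)],
                design.tau,
                covariate_aware=len(active) > 0,
            )
            if design.no_skip:
                ceiling = int(allocations[: c * n_c].max()) + 1
                doses = np.minimum(doses, ceiling)
        out_rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(2, c))
        )
        p_true = truth.prob_matrix(X_c)[np.arange(n_c), doses]
        y = (out_rng.random(n_c) < p_true).astype(int)

        sl = slice(c * n_c, (c + 1) * n_c)
        allocations[sl] = doses
        cohort_of[sl] = c
        data = data.append(doses, X_c, y)

        ratios: dict[int, float] = {}
        if is_cchange:
            post = _fit(truth, design, data, active, c, seed)
            newly = []
            for j_pos, j in enumerate(candidates):
                if inclusion.included[j_pos]:
                    ratios[j] = float("nan")
                    continue
                cols_with = tuple(sorted(set(active) | {j}))
                post_with = _fit(truth, design, data, cols_with, c, seed)
                ratios[j] = cchange_ratio(
                    data, post, post_with, design.tau,
                    cols_without=active, cols_with=cols_with,
                )
                newly.append((j_pos, j, cols_with, post_with))
            inclusion = update_inclusion(
                inclusion,
                [0.0 if np.isnan(ratios[j]) else ratios[j] for j in candidates],
                design.cchange_thresholds,
            )
            new_active = tuple(sorted(candidates[i] for i in range(len(candidates))
                                      if inclusion.included[i]))
            if new_active != active:
                reused = [pw for (_, j, cw, pw) in newly if cw == new_active]
                post = reused[0] if reused else _fit(
                    truth, design, data, new_active, c, seed
                )
                active = new_active
        else:
            post = _fit(truth, design, data, active, c, seed)
        if post.diagnostics.get("convergence_flag"):
            flags.append(f"cohort {c}: convergence flag")
        logs.append(
            CohortLog(
                cohort=c,
                doses=doses.copy(),
                ratios=ratios,
                included_after=tuple(active),
                phat_reference=post.prob_curve(np.zeros(len(active))),
            )
        )

    return TrialRecord(
        data=data,
        cohort_of=cohort_of,
        allocations=allocations,
        inclusion=inclusion,
        final_posterior=post,
        final_covariate_indices=active,
        cohorts=logs,
        seed=seed,
        flags=flags,
    )
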