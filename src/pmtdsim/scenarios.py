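"""True dose-toxicity models, covariate distributions and scenario calibration.

A *scenario truth* is the data-generating mechanism of a simulated trial:
a dose grid, a dose-toxicity family (two-parameter logistic on the
log-dose-ratio scale, or a saturating Emax form on the logit scale),
optional linear covariate effects, and the sampling distribution of the
covariates.  The module also provides the calibration step that chooses
family coefficients so that toxicity probabilities *averaged over the
covariate distribution* hit a target marginal curve, which is how
comparable scenarios with and without covariate effects are built.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, logit

__all__ = [
    "DoseGrid",
    "Covariate",
    "CovariateSpec",
    "ScenarioTruth",
    "CalibrationResult",
    "logistic_prob",
    "emax_prob",
    "closest_dose",
    "true_pmtd",
    "marginal_prob",
    "marginal_probs",
    "calibrate_truth",
    "pmtd_distribution",
]

NORMAL = "normal"
BERNOULLI = "bernoulli"


@dataclass(frozen=True)
class DoseGrid:
    """Ordered dose amounts (mg) with a positive reference dose."""

    doses: tuple[float, ...]
    reference_dose: float

    def __post_init__(self) -> None:
        doses = tuple(float(d) for d in self.doses)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "reference_dose", float(self.reference_dose))
        if len(doses) == 0:
            raise ValueError("dose grid must contain at least one dose")
        if any(d <= 0 for d in doses):
            raise ValueError("doses must be positive")
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError("doses must be strictly increasing")
        if self.reference_dose <= 0:
            raise ValueError("reference dose must be positive")

    @property
    def n_doses(self) -> int:
        return len(self.doses)

    def log_ratio(self) -> np.ndarray:
        """log(d_k / d_r) for every grid dose."""
        cached = getattr(self, "_log_ratio", None)
        if cached is None:
            cached = np.log(np.asarray(self.doses) / self.reference_dose)
            object.__setattr__(self, "_log_ratio", cached)
        return cached


@dataclass(frozen=True)
class Covariate:
    """One covariate descriptor: continuous normal or binary Bernoulli."""

    kind: str
    mean: float = 0.0
    sd: float = 1.0
    prob: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in (NORMAL, BERNOULLI):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == NORMAL and self.sd <= 0:
            raise ValueError("normal covariate needs sd > 0")
        if self.kind == BERNOULLI and not 0 < self.prob < 1:
            raise ValueError("Bernoulli probability must be in (0,1)")

    @staticmethod
    def normal(mean: float = 0.0, sd: float = 1.0) -> "Covariate":
        return Covariate(NORMAL, mean=mean, sd=sd)

    @staticmethod
    def bernoulli(prob: float = 0.5) -> "Covariate":
        return Covariate(BERNOULLI, prob=prob)


def _as_matrix(correlation, k: int) -> np.ndarray:
    rho = np.asarray(correlation, dtype=float)
    if rho.shape != (k, k):
        raise ValueError(f"correlation must be {k}x{k}")
    if not np.allclose(rho, rho.T):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(rho), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    if np.any(np.linalg.eigvalsh(rho) <= 0):
        raise ValueError("correlation matrix must be positive definite")
    return rho


@dataclass(frozen=True)
class CovariateSpec:
    """Joint covariate distribution: a correlated normal block plus
    independent Bernoulli columns, in declaration order."""

    covariates: tuple[Covariate, ...] = ()
    correlation: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(self.covariates))
        k = sum(1 for c in self.covariates if c.kind == NORMAL)
        if self.correlation is not None:
            rho = _as_matrix(self.correlation, k)
            object.__setattr__(
                self, "correlation", tuple(tuple(row) for row in rho)
            )

    @property
    def p(self) -> int:
        return len(self.covariates)

    @property
    def kinds(self) -> tuple[str, ...]:
        return tuple(c.kind for c in self.covariates)

    def _rho(self) -> np.ndarray:
        k = sum(1 for c in self.covariates if c.kind == NORMAL)
        if self.correlation is None:
            return np.eye(k)
        return np.asarray(self.correlation, dtype=float)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw an (n, p) covariate matrix."""
        if n < 1:
            raise ValueError("n must be >= 1")
        out = np.empty((n, self.p))
        normals = [i for i, c in enumerate(self.covariates) if c.kind == NORMAL]
        if normals:
            rho = self._rho()
            z = rng.multivariate_normal(
                np.zeros(len(normals)), rho, size=n, method="cholesky"
            )
            for j, i in enumerate(normals):
                c = self.covariates[i]
                out[:, i] = c.mean + c.sd * z[:, j]
        for i, c in enumerate(self.covariates):
            if c.kind == BERNOULLI:
                out[:, i] = (rng.random(n) < c.prob).astype(float)
        return out

    def quadrature(self, n_nodes: int = 40) -> tuple[np.ndarray, np.ndarray]:
        """Tensor-product nodes/weights integrating against the covariate law.

        Gauss-Hermite per continuous dimension (mapped through the Cholesky
        factor of the correlation), exact two-point enumeration per binary
        dimension.  Returns (nodes (M, p), weights (M,)), weights sum to 1.
        """
        normals = [i for i, c in enumerate(self.covariates) if c.kind == NORMAL]
        if len(normals) > 3:
            raise ValueError(
                "quadrature supports at most 3 continuous covariates; "
                "use Monte Carlo"
            )
        axes_nodes: list[np.ndarray] = []
        axes_weights: list[np.ndarray] = []
        for c in self.covariates:
            if c.kind == NORMAL:
                z, w = hermgauss(n_nodes)
                axes_nodes.append(z * math.sqrt(2.0))  # standard normal scale
                axes_weights.append(w / math.sqrt(math.pi))
            else:
                axes_nodes.append(np.array([0.0, 1.0]))
                axes_weights.append(np.array([1.0 - c.prob, c.prob]))
        if not axes_nodes:
            return np.empty((1, 0)), np.ones(1)
        mesh = np.meshgrid(*axes_nodes, indexing="ij")
        wmesh = np.meshgrid(*axes_weights, indexing="ij")
        nodes = np.column_stack([m.ravel() for m in mesh])
        weights = np.prod(np.stack([w.ravel() for w in wmesh]), axis=0)
        if normals:
            L = np.linalg.cholesky(self._rho())
            z = nodes[:, normals] @ L.T
            for j, i in enumerate(normals):
                c = self.covariates[i]
                nodes[:, i] = c.mean + c.sd * z[:, j]
        return nodes, weights


@dataclass(frozen=True)
class ScenarioTruth:
    """True data-generating dose-toxicity model.

    ``coeffs`` is (alpha, beta) for the logistic family and
    (alpha1, alpha2, alpha3) for the Emax family; ``gamma`` holds the linear
    covariate coefficients on the logit scale.
    """

    family: str
    dose_grid: DoseGrid
    coeffs: tuple[float, ...]
    gamma: tuple[float, ...] = ()
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    tau: float = 0.25
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "coeffs", tuple(float(c) for c in self.coeffs))
        object.__setattr__(self, "gamma", tuple(float(g) for g in self.gamma))
        if self.family not in ("logistic", "emax"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "logistic" and len(self.coeffs) != 2:
            raise ValueError("logistic family needs (alpha, beta)")
        if self.family == "emax":
            if len(self.coeffs) != 3:
                raise ValueError("emax family needs (alpha1, alpha2, alpha3)")
            if self.coeffs[2] <= 0:
                raise ValueError("emax alpha3 must be positive")
        if len(self.gamma) != self.covariate_spec.p:
            raise ValueError("gamma length must match covariate spec")
        if not 0 < self.tau < 1:
            raise ValueError("tau must be in (0,1)")

    @property
    def p(self) -> int:
        return self.covariate_spec.p

    def dose_term(self) -> np.ndarray:
        """Dose contribution to the logit, per grid dose."""
        d = np.asarray(self.dose_grid.doses)
        if self.family == "logistic":
            alpha, beta = self.coeffs
            return alpha + beta * self.dose_grid.log_ratio()
        a1, a2, a3 = self.coeffs
        return a1 + a2 * d / (d + a3)

    def prob_matrix(self, X: np.ndarray) -> np.ndarray:
        """True DLT probabilities, shape (n, K), for covariate rows X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.p:
            raise ValueError(
                f"expected {self.p} covariates, got {X.shape[1]}"
            )
        shift = X @ np.asarray(self.gamma) if self.p else np.zeros(X.shape[0])
        return expit(self.dose_term()[None, :] + shift[:, None])

    def prob(self, dose_index: int, covariates: Sequence[float] = ()) -> float:
        x = np.asarray(covariates, dtype=float).reshape(1, -1)
        if self.p == 0:
            x = x.reshape(1, 0)
        return float(self.prob_matrix(x)[0, int(dose_index)])


def _check_dims(covariates, gamma) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(covariates, dtype=float).ravel()
    g = np.asarray(gamma, dtype=float).ravel()
    if x.size != g.size:
        raise ValueError(
            f"covariates ({x.size}) and gamma ({g.size}) lengths differ"
        )
    return x, g


def logistic_prob(
    coeffs: tuple[float, float],
    dose_grid: DoseGrid,
    dose_index: int,
    covariates: Sequence[float] = (),
    gamma: Sequence[float] = (),
) -> float:
    """logit^-1(alpha + beta*log(d_k/d_r) + gamma.x)."""
    alpha, beta = coeffs
    x, g = _check_dims(covariates, gamma)
    eta = alpha + beta * dose_grid.log_ratio()[int(dose_index)] + x @ g
    return float(expit(eta))


def emax_prob(
    coeffs: tuple[float, float, float],
    dose_grid: DoseGrid,
    dose_index: int,
    covariates: Sequence[float] = (),
    gamma: Sequence[float] = (),
) -> float:
    """logit^-1(alpha1 + alpha2*d/(d+alpha3) + gamma.x)."""
    a1, a2, a3 = coeffs
    if a3 <= 0:
        raise ValueError("emax alpha3 must be positive")
    x, g = _check_dims(covariates, gamma)
    d = dose_grid.doses[int(dose_index)]
    return float(expit(a1 + a2 * d / (d + a3) + x @ g))


def closest_dose(probs: np.ndarray, tau: float) -> int:
    """Dose index minimizing |p - tau|; ties resolved to the highest dose."""
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        raise ValueError("empty probability vector")
    dist = np.abs(probs - tau)
    # argmin on the reversed vector picks the last minimiser
    return int(probs.size - 1 - np.argmin(dist[::-1]))


def closest_dose_rows(prob_matrix: np.ndarray, tau: float) -> np.ndarray:
    """Row-wise :func:`closest_dose` for an (n, K) probability matrix."""
    pm = np.atleast_2d(np.asarray(prob_matrix, dtype=float))
    dist = np.abs(pm - tau)[:, ::-1]
    return pm.shape[1] - 1 - np.argmin(dist, axis=1)


def true_pmtd(truth: ScenarioTruth, covariates: Sequence[float] = ()) -> int:
    """Personalised MTD under the true model for one covariate vector."""
    x = np.asarray(covariates, dtype=float).reshape(1, -1)
    if truth.p == 0:
        x = x.reshape(1, 0)
    return int(closest_dose_rows(truth.prob_matrix(x), truth.tau)[0])


def true_pmtd_rows(truth: ScenarioTruth, X: np.ndarray) -> np.ndarray:
    return closest_dose_rows(truth.prob_matrix(X), truth.tau)


def marginal_prob(
    truth: ScenarioTruth, dose_index: int, n_nodes: int = 40
) -> float:
    """Toxicity probability at a dose averaged over the covariate law."""
    return float(marginal_probs(truth, n_nodes=n_nodes)[int(dose_index)])


def marginal_probs(truth: ScenarioTruth, n_nodes: int = 40) -> np.ndarray:
    """Marginal toxicity probabilities over the whole dose grid."""
    if truth.p == 0:
        return truth.prob_matrix(np.empty((1, 0)))[0]
    nodes, weights = truth.covariate_spec.quadrature(n_nodes)
    return weights @ truth.prob_matrix(nodes)


@dataclass(frozen=True)
class CalibrationResult:
    truth: ScenarioTruth
    targets: tuple[float, ...]
    achieved: tuple[float, ...]
    residuals: tuple[float, ...]

    @property
    def max_abs_residual(self) -> float:
        return max(abs(r) for r in self.residuals)


def _anchor_pair(targets: np.ndarray, tau: float) -> tuple[int, int]:
    mtd = closest_dose(targets, tau)
    nb = mtd + 1 if mtd + 1 < targets.size else mtd - 1
    return mtd, nb


_LOGIT_CLIP = 5e-4


def calibrate_truth(
    target_marginals: Sequence[float],
    family: str = "logistic",
    gamma: Sequence[float] = (),
    covariate_spec: CovariateSpec | None = None,
    dose_grid: DoseGrid | None = None,
    tau: float = 0.25,
    name: str = "",
    n_nodes: int = 40,
) -> CalibrationResult:
    """Choose family coefficients so marginal probabilities match targets.

    With no covariates and the logistic family, (alpha, beta) is solved in
    closed form from two anchor cells (the dose closest to ``tau`` and its
    neighbour); otherwise the remaining coefficients are fitted by least
    squares on logit-scale marginals with ``gamma`` held fixed.
    """
    targets = np.asarray(target_marginals, dtype=float)
    if np.any(targets < 0) or np.any(targets >= 1):
        raise ValueError("target marginals must lie in [0,1)")
    if np.any(np.diff(targets) <= 0):
        raise ValueError("target marginals must be strictly increasing")
    spec = covariate_spec or CovariateSpec()
    gamma = tuple(float(g) for g in gamma)
    if len(gamma) != spec.p:
        raise ValueError("gamma length must match covariate spec")
    if dose_grid is None:
        dose_grid = DoseGrid((1, 3, 5, 7, 9), 5)
    if targets.size != dose_grid.n_doses:
        raise ValueError("one target per grid dose required")

    lr = dose_grid.log_ratio()
    t_logit = logit(np.clip(targets, _LOGIT_CLIP, 1 - _LOGIT_CLIP))

    if family == "logistic" and spec.p == 0:
        i, j = _anchor_pair(targets, tau)
        A = np.array([[1.0, lr[i]], [1.0, lr[j]]])
        alpha, beta = np.linalg.solve(A, logit(targets[[i, j]]))
        coeffs = (float(alpha), float(beta))
    else:
        def make(theta: np.ndarray) -> ScenarioTruth:
            if family == "logistic":
                coeffs = (theta[0], math.exp(theta[1]))
            else:
                coeffs = (theta[0], theta[1], math.exp(theta[2]))
            return ScenarioTruth(
                family, dose_grid, coeffs, gamma, spec, tau, name
            )

        def resid(theta: np.ndarray) -> np.ndarray:
            m = marginal_probs(make(theta), n_nodes=n_nodes)
            return logit(np.clip(m, _LOGIT_CLIP, 1 - _LOGIT_CLIP)) - t_logit

        if family == "logistic":
            i, j = _anchor_pair(targets, tau)
            A = np.array([[1.0, lr[i]], [1.0, lr[j]]])
            a0, b0 = np.linalg.solve(A, logit(targets[[i, j]]))
            x0 = np.array([a0, math.log(max(b0, 1e-3))])
        elif family == "emax":
            x0 = np.array([t_logit[0] - 0.5, t_logit[-1] - t_logit[0] + 1.0, math.log(dose_grid.reference_dose)])
        else:
            raise ValueError(f"unknown family {family!r}")
        sol = optimize.least_squares(resid, x0, method="lm", xtol=1e-12)
        if not sol.success:
            raise RuntimeError(
                f"calibration failed: {sol.message}; residuals {sol.fun}"
            )
        theta = sol.x
        if family == "logistic":
            coeffs = (float(theta[0]), float(math.exp(theta[1])))
        else:
            coeffs = (float(theta[0]), float(theta[1]), float(math.exp(theta[2])))

    truth = ScenarioTruth(family, dose_grid, coeffs, gamma, spec, tau, name)
    achieved = marginal_probs(truth, n_nodes=n_nodes)
    return CalibrationResult(
        truth=truth,
        targets=tuple(float(t) for t in targets),
        achieved=tuple(float(a) for a in achieved),
        residuals=tuple(float(a - t) for a, t in zip(achieved, targets)),
    )


def pmtd_distribution(
    truth: ScenarioTruth, n_draws: int = 100_000, seed: int = 0
) -> np.ndarray:
    """Monte Carlo distribution of the personalised MTD over the population."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if truth.p == 0:
        out = np.zeros(truth.dose_grid.n_doses)
        out[true_pmtd(truth)] = 1.0
        return out
    rng = np.random.default_rng(seed)
    X = truth.covariate_spec.sample(n_draws, rng)
    idx = true_pmtd_rows(truth, X)
    return np.bincount(idx, minlength=truth.dose_grid.n_doses) / n_draws
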