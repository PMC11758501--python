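"""Prior families on (intercept, log-slope) and covariate coefficients.

Four covariate-coefficient priors are supported:

* ``None`` — no covariates in the model (plain two-parameter fit);
* :class:`FlatNormal` — independent N(0, sigma^2), no shrinkage;
* :class:`BayesianLasso` — Laplace(0, lambda_g) with density
  (lambda/2) exp(-lambda |g|), one penalisation parameter per covariate
  *group* (continuous vs binary) with an InverseGamma(delta, delta)
  hyperprior on each lambda_g;
* :class:`SpikeSlab` — a two-component normal mixture per coefficient with
  a Beta-distributed mixture weight.  As printed in the source model,
  (1 - m_j) multiplies the low-variance spike; ``weight_on_spike=False``
  flips that convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import logit

from .scenarios import BERNOULLI, NORMAL

__all__ = [
    "FlatNormal",
    "BayesianLasso",
    "SpikeSlab",
    "PriorSpec",
    "default_base_mean",
    "default_base_cov",
    "log_prior",
]


def default_base_mean() -> tuple[float, float]:
    """Weakly-informative default: prior median DLT rate 0.1 at d_r."""
    return (float(logit(0.1)), 0.0)


def default_base_cov() -> tuple[tuple[float, float], tuple[float, float]]:
    return ((4.0, 0.0), (0.0, 4.0))


@dataclass(frozen=True)
class FlatNormal:
    variance: float = 4.0

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("variance must be positive")


@dataclass(frozen=True)
class BayesianLasso:
    """Per-group hyperprior shape/rate for the penalisation parameter.

    ``fixed_lambda`` bypasses the hyperprior and pins every group's
    penalisation parameter (useful to disable shrinkage: a tiny rate gives
    an essentially flat Laplace).
    """

    delta_continuous: float = 0.4
    delta_binary: float = 0.4
    fixed_lambda: float | None = None

    def __post_init__(self) -> None:
        if self.delta_continuous <= 0 or self.delta_binary <= 0:
            raise ValueError("delta hyperparameters must be positive")
        if self.fixed_lambda is not None and self.fixed_lambda <= 0:
            raise ValueError("fixed_lambda must be positive")

    def delta_for(self, kind: str) -> float:
        return self.delta_continuous if kind == NORMAL else self.delta_binary


@dataclass(frozen=True)
class SpikeSlab:
    b1: float = 2.0
    b2: float = 2.0
    slab_variance: float = 4.0
    spike_variance_continuous: float = 0.05
    spike_variance_binary: float = 0.05
    # as printed: weight (1 - m_j) on the low-variance component
    weight_on_spike: bool = True

    def __post_init__(self) -> None:
        if min(self.b1, self.b2) <= 0:
            raise ValueError("Beta parameters must be positive")
        if self.slab_variance <= 0:
            raise ValueError("slab variance must be positive")
        for v in (self.spike_variance_continuous, self.spike_variance_binary):
            if v <= 0:
                raise ValueError("spike variance must be positive")
            if v >= self.slab_variance:
                raise ValueError("spike variance must be below slab variance")

    def spike_variance_for(self, kind: str) -> float:
        return (
            self.spike_variance_continuous
            if kind == NORMAL
            else self.spike_variance_binary
        )


CovariatePrior = FlatNormal | BayesianLasso | SpikeSlab


@dataclass(frozen=True)
class PriorSpec:
    """Bivariate normal on (alpha, log beta) plus a covariate-prior variant."""

    base_mean: tuple[float, float] = field(default_factory=default_base_mean)
    base_cov: tuple[tuple[float, float], tuple[float, float]] = field(
        default_factory=default_base_cov
    )
    covariate: CovariatePrior | None = None

    def __post_init__(self) -> None:
        cov = np.asarray(self.base_cov, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ValueError("base covariance must be symmetric 2x2")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("base covariance must be positive definite")

    def base_mean_arr(self) -> np.ndarray:
        return np.asarray(self.base_mean, dtype=float)

    def base_cov_arr(self) -> np.ndarray:
        return np.asarray(self.base_cov, dtype=float)


def _laplace_logpdf(g: np.ndarray, lam: np.ndarray) -> np.ndarray:
    return np.log(lam / 2.0) - lam * np.abs(g)


def log_prior(
    alpha: float,
    log_beta: float,
    gamma: Sequence[float],
    spec: PriorSpec,
    kinds: Sequence[str] = (),
    lambdas: dict[str, float] | None = None,
    mixture_weights: Sequence[float] | None = None,
) -> float:
    """Joint log prior density at one parameter point.

    ``lambdas`` (per covariate group) are required for the Lasso variant,
    ``mixture_weights`` (per covariate) for Spike-and-Slab.  Out-of-support
    auxiliaries (lambda <= 0, m outside [0,1]) return -inf.
    """
    gamma = np.asarray(gamma, dtype=float)
    kinds = tuple(kinds)
    if gamma.size != len(kinds):
        raise ValueError("gamma and kinds must align")
    lp = float(
        stats.multivariate_normal.logpdf(
            [alpha, log_beta], spec.base_mean_arr(), spec.base_cov_arr()
        )
    )
    cov = spec.covariate
    if gamma.size == 0:
        return lp
    if cov is None:
        raise ValueError("covariate coefficients present but no covariate prior")
    if isinstance(cov, FlatNormal):
        if lambdas or mixture_weights:
            raise ValueError("FlatNormal takes no auxiliaries")
        lp += float(
            np.sum(stats.norm.logpdf(gamma, 0.0, np.sqrt(cov.variance)))
        )
    elif isinstance(cov, BayesianLasso):
        if cov.fixed_lambda is not None:
            lp += float(np.sum(_laplace_logpdf(gamma, cov.fixed_lambda)))
            return lp
        if lambdas is None:
            raise ValueError("Lasso prior requires lambda per covariate group")
        groups = sorted(set(kinds))
        if set(lambdas) != set(groups):
            raise ValueError(f"need one lambda per group {groups}")
        for g in groups:
            lam = float(lambdas[g])
            if lam <= 0:
                return -np.inf
            delta = cov.delta_for(g)
            lp += float(stats.invgamma.logpdf(lam, a=delta, scale=delta))
            idx = [i for i, k in enumerate(kinds) if k == g]
            lp += float(np.sum(_laplace_logpdf(gamma[idx], lam)))
    elif isinstance(cov, SpikeSlab):
        if mixture_weights is None:
            raise ValueError("SpikeSlab prior requires mixture weights m_j")
        m = np.asarray(mixture_weights, dtype=float)
        if m.size != gamma.size:
            raise ValueError("one mixture weight per covariate required")
        if np.any((m < 0) | (m > 1)):
            return -np.inf
        for j, kind in enumerate(kinds):
            nu = cov.spike_variance_for(kind)
            w_spike = (1.0 - m[j]) if cov.weight_on_spike else m[j]
            with np.errstate(divide="ignore"):
                comp = np.array(
                    [
                        np.log(w_spike)
                        + stats.norm.logpdf(gamma[j], 0.0, np.sqrt(nu)),
                        np.log(1.0 - w_spike)
                        + stats.norm.logpdf(
                            gamma[j], 0.0, np.sqrt(cov.slab_variance)
                        ),
                    ]
                )
            lp += float(np.logaddexp(comp[0], comp[1]))
            lp += float(stats.beta.logpdf(m[j], cov.b1, cov.b2))
    else:  # pragma: no cover - exhaustive variants
        raise TypeError(f"unknown covariate prior {type(cov)}")
    if not np.isfinite(lp):
        return -np.inf if lp == -np.inf else lp
    return lp
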