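import numpy as np
import pytest

from pmtdsim.fixtures import build_truths, load_marginal_table
from pmtdsim.scenarios import Covariate, CovariateSpec, DoseGrid


@pytest.fixture(scope="session")
def dose_grid() -> DoseGrid:
    return DoseGrid((1, 3, 5, 7, 9), 5)


@pytest.fixture(scope="session")
def marginal_table() -> dict:
    return load_marginal_table()


@pytest.fixture(scope="session")
def nocov_truths():
    """The five bundled no-covariate logistic truths, keyed d1..d5."""
    return {k: r.truth for k, r in build_truths().items()}


@pytest.fixture(scope="session")
def two_normal_spec() -> CovariateSpec:
    return CovariateSpec((Covariate.normal(), Covariate.normal()))


@pytest.fixture(scope="session")
def mixed_spec() -> CovariateSpec:
    return CovariateSpec((Covariate.normal(), Covariate.bernoulli(0.5)))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
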