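import numpy as np
import pytest

from spikemaxent import (
    MarginalSpec,
    TruncatedSupport,
    fit_maxent,
    truncate_support,
)


@pytest.fixture(scope="session")
def rate3():
    return MarginalSpec(3.0)


@pytest.fixture(scope="session")
def support3(rate3):
    return truncate_support(rate3, rate3)


@pytest.fixture(scope="session")
def me_rho02(rate3, support3):
    """Maximum entropy model, Poisson(3) marginals, correlation 0.2."""
    return fit_maxent(rate3, rate3, 0.2, support3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
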