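import numpy as np
import pytest

import childmort as cm
from childmort.b3 import MCMCConfig


@pytest.fixture(scope="session")
def small_world():
    """A 10-country synthetic world shared across estimation tests."""
    return cm.generate_world(seed=0, n_countries=10)


@pytest.fixture(scope="session")
def small_mcmc():
    return MCMCConfig(chains=4, warmup=300, samples=400)


@pytest.fixture(scope="session")
def small_fit(small_world, small_mcmc):
    """Joint fit of the 10-country world's U5MR observations."""
    u5 = [r for r in small_world.observations if r.indicator == "U5MR"]
    basis = cm.build_spline_basis(1985.5, 2019.5)
    return cm.fit_b3(u5, basis, mcmc=small_mcmc, seed=1)
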