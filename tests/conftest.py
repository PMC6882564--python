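import numpy as np
import pytest
from hypothesis import settings

from ctdose import McmcConfig, default_arm_spec, generate_cohort

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def arm_120():
    return default_arm_spec(120, n=100, seed=11)


@pytest.fixture(scope="session")
def arm_100():
    return default_arm_spec(100, n=100, seed=12)


@pytest.fixture(scope="session")
def cohort_120(arm_120):
    return generate_cohort(arm_120, moment_match_flag=True)


@pytest.fixture(scope="session")
def cohort_100(arm_100):
    return generate_cohort(arm_100, moment_match_flag=True)


@pytest.fixture(scope="session")
def small_mcmc():
    """Reduced sampler configuration for fast unit tests."""
    return McmcConfig(n_chains=4, draws_per_chain=3000, burn_in=500, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
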