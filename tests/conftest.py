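import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mipdsim import config, scenarios
from mipdsim.population import expand_virtual, generate_source_cohort

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def poppk():
    return config.default_poppk_params()


@pytest.fixture(scope="session")
def er():
    return config.default_er_params()


@pytest.fixture(scope="session")
def small_population(poppk):
    """Default cohort expanded 20x: 3,880 virtual patients."""
    cfg = config.default_cohort_config().replace(n_expand=20)
    cohort = generate_source_cohort(cfg, seed=11)
    return expand_virtual(cohort, poppk, cfg.n_expand, seed=22)


@pytest.fixture(scope="session")
def scenario_suite(small_population, poppk, er):
    """All four paired dosing scenarios on the small population."""
    return scenarios.run_all(small_population, poppk, er, seed=33)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
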