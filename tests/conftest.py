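import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from reefseed import SamplerSpec
from reefseed.moorea import default_params
from reefseed.simulate import default_scenario, simulate_survey

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sampler():
    return SamplerSpec()


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_160_909)


@pytest.fixture(scope="session")
def survey():
    """A moderate synthetic survey at reef-like magnitudes (fixed seed)."""
    return simulate_survey(default_scenario(seed=7))


@pytest.fixture(scope="session")
def small_survey():
    """A small synthetic survey for fast I/O and pipeline tests."""
    scenario = default_scenario(seed=11)
    truths = tuple(
        type(t)(**{**t.__dict__, "n_tiles": 4, "n_quadrats": 6, "n_images": 5,
                   "n_colonies": 20})
        for t in scenario.truths)
    scenario = type(scenario)(**{**scenario.__dict__, "truths": truths,
                                 "n_allometry_pairs": 10})
    return simulate_survey(scenario)
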