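import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", message=".*ArviZ.*")

from heatfish import synthetic_data as synth  # noqa: E402


@pytest.fixture(scope="session")
def small_config() -> synth.SimConfig:
    """Small population: 4 cohorts, enough fish for counting checks."""
    return synth.SimConfig(
        seed=7,
        recruits_per_cohort=200,
        cohort_first=1988,
        cohort_last=1991,
        catch_first=1989,
        catch_last=2000,
    )


@pytest.fixture(scope="session")
def fish_small(small_config):
    return synth.simulate_cohorts(small_config)


@pytest.fixture(scope="session")
def catch_small(small_config, fish_small):
    return synth.simulate_catch(fish_small, small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
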