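import numpy as np
import pytest
from hypothesis import settings

from isiwin import EstimatorConfig, GaussianModel, PopulationParams, SubjectParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def fig_profile() -> GaussianModel:
    """The worked single-subject profile: peak 1 mV at 40 ms, sigma 17.5 ms,
    whose two-sigma window is [5, 75] ms (length 70 ms)."""
    return GaussianModel(amplitude=1.0, center=40.0, width=17.5)


@pytest.fixture
def noiseless_subject(fig_profile) -> SubjectParams:
    return SubjectParams(profile=fig_profile, t_delay=195.5, baseline_mep=0.05,
                         noise_cv=0.0)


@pytest.fixture
def noisy_subject(fig_profile) -> SubjectParams:
    return SubjectParams(profile=fig_profile, t_delay=195.5, baseline_mep=0.05,
                         noise_cv=0.3)


@pytest.fixture
def population() -> PopulationParams:
    return PopulationParams()


@pytest.fixture
def base_config() -> EstimatorConfig:
    return EstimatorConfig(method="gpr", n_ini=7, search_lower=0.0,
                           search_upper=245.0, seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
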