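import numpy as np
import pytest
from hypothesis import settings

from accelcox.coxgam import ModelSpec, fit
from accelcox.features import default_bins
from accelcox.simulate import SimConfig, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bins():
    return default_bins()


@pytest.fixture(scope="session")
def small_cohort(bins):
    """n=400 synthetic cohort with an elevated baseline hazard (~10% events)."""
    cfg = SimConfig(n_participants=400, baseline_hazard=0.0165, seed=11)
    table, _ = generate_cohort(cfg, bins)
    return table


@pytest.fixture(scope="session")
def mid_cohort(bins):
    cfg = SimConfig(n_participants=1500, baseline_hazard=0.0165, seed=5)
    table, _ = generate_cohort(cfg, bins)
    return table


@pytest.fixture(scope="session")
def fit_unadjusted(small_cohort, bins):
    return fit(small_cohort, ModelSpec(adjusted=False), bins)


@pytest.fixture(scope="session")
def fit_adjusted(mid_cohort, bins):
    return fit(mid_cohort, ModelSpec(adjusted=True), bins)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
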