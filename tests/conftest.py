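import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trifret.synthetic import KineticConfig, PhotoConfig, simulate_dataset

settings.register_profile(
    "repro", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Small noiseless dataset: (timelines, traces, truth, photo)."""
    kin = KineticConfig(n_molecules=25, seed=3)
    photo = PhotoConfig.noiseless()
    timelines, traces, truth = simulate_dataset(kin, photo, duration_s=80.0)
    return timelines, traces, truth, photo


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default-noise dataset at the original-orientation condition."""
    kin = KineticConfig.for_mean_lag(4.9, n_molecules=60, seed=21)
    photo = PhotoConfig()
    timelines, traces, truth = simulate_dataset(kin, photo, duration_s=100.0)
    return timelines, traces, truth, photo


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
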