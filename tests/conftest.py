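import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from polarppg.signal_io import RunConfig
from polarppg.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def run_config():
    return RunConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 60-s default-conditions cohort (seed fixed)."""
    return generate_cohort(CohortConfig(duration_s=60.0, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20250926)


def make_beat_train(fs=25.0, duration_s=10.0, rate_hz=1.2, amp=1.0, baseline=100.0):
    """Simple reference beat train: baseline with sinusoidal dips (helper)."""
    t = np.arange(int(round(duration_s * fs))) / fs
    return baseline - amp * 0.5 * (1 + np.sin(2 * np.pi * rate_hz * t)), t
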