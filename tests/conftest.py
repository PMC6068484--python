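import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import edfnn

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quiet_profile():
    """A noiseless fixed-cadence subject: 1.0 s cycles, exact structure."""
    return edfnn.SubjectProfile(cadence_mean=1.0, cadence_std=0.0, noise_std=0.0)


@pytest.fixture(scope="session")
def quiet_recording(quiet_profile):
    rec, truth = edfnn.generate_recording(quiet_profile, 12, seed=7)
    return rec, truth


@pytest.fixture(scope="session")
def small_labeled(quiet_recording):
    rec, _ = quiet_recording
    return edfnn.recording_to_labeled(rec)


@pytest.fixture(scope="session")
def small_embedded(small_labeled):
    return edfnn.apply_exponential_window(small_labeled, edfnn.DelayConfig())
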