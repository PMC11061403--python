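import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def gains():
    from ctmaug.core import default_gains
    return default_gains()


@pytest.fixture(scope="session")
def noise_free_target(gains):
    """Analytic spectrum of the default gains on an epoch-like 0.4 Hz grid."""
    from ctmaug.core import analytic_spectrum
    freqs = np.arange(0.4, 45.0, 0.4)
    return analytic_spectrum(gains, freqs=freqs)


@pytest.fixture(scope="session")
def quiet_subject():
    """High-SNR synthetic subject: strong planted contrast, minimal noise."""
    from ctmaug.synth import CohortSpec, make_subject
    spec = CohortSpec(n_subjects=1, n_epochs_per_condition=36,
                      subject_noise_range=(0.5, 0.5), epoch_power_jitter=0.0,
                      seed=101)
    return make_subject(spec, 0)
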