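import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def gaussian_trace(n, apex, amplitude, sigma, baseline=0.0):
    t = np.arange(n, dtype=float)
    return baseline + amplitude * np.exp(-0.5 * ((t - apex) / sigma) ** 2)


@pytest.fixture
def standard_peak():
    """Clean Gaussian elution peak used across de-noising tests."""
    return gaussian_trace(256, 128.0, 100.0, 8.0, baseline=60.0)
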