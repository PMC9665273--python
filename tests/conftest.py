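import numpy as np
import pytest

from physiofc import SimParams, generate_subject


@pytest.fixture(scope="session")
def default_subject():
    """One full-size simulated subject with all corruption on (defaults)."""
    return generate_subject(SimParams(seed=3))


@pytest.fixture(scope="session")
def clean_subject():
    """Noise-free, spike-free subject: observed = neural + contamination
    + drift exactly."""
    return generate_subject(SimParams(seed=3, noise_sd=0.0, spike_rate=0.0))


@pytest.fixture(scope="session")
def small_params():
    """Small, fast generator settings for unit-level checks."""
    return SimParams(n_regions=10, n_volumes=120, n_discard=4, seed=11,
                     target_corr=None)


def pytest_configure(config):
    # keep hypothesis deterministic across runs
    try:
        from hypothesis import settings, HealthCheck

        settings.register_profile(
            "ci", derandomize=True, deadline=None,
            suppress_health_check=[HealthCheck.too_slow])
        settings.load_profile("ci")
    except ImportError:
        pass
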