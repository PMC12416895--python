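import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pulsecomp import CohortSpec, FlowWaveform, forward_windkessel_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_sine(q0: float = 6.0, q_mean: float = 12.0, n: int = 64, T: float = 1.0):
    """One cycle of Q(t) = q_mean + q0*sin(2*pi*t/T)."""
    t = np.arange(n) * (T / n)
    return FlowWaveform(t, q_mean + q0 * np.sin(2 * np.pi * t / T), T)


@pytest.fixture(scope="session")
def sine_wave():
    return make_sine()


@pytest.fixture(scope="session")
def default_cohort():
    """A full four-territory paired cohort at the default study conditions."""
    return forward_windkessel_cohort(CohortSpec(), seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    return forward_windkessel_cohort(CohortSpec(n_subjects=4), seed=11)
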