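import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dcmerp import neural as nm
from dcmerp.observation import sample_leadfield
from dcmerp.simulate import default_grid


@pytest.fixture(scope="session")
def two_source():
    """Forward 0->1, backward 1->0, stimulus into source 0."""
    return nm.two_source_spec()


@pytest.fixture(scope="session")
def theta0(two_source):
    return nm.ParameterVector(two_source)


@pytest.fixture(scope="session")
def stim():
    return nm.StimulusInput()


@pytest.fixture(scope="session")
def short_grid():
    """0-300 ms at 250 Hz: cheap but covers the evoked transient."""
    return default_grid(window_ms=(0.0, 300.0))


@pytest.fixture(scope="session")
def leadfield(two_source):
    return sample_leadfield(8, two_source.n_sources, seed=42)


@pytest.fixture(scope="session")
def full_grid():
    return default_grid()
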