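import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from emgintent import preprocess, synth

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def healthy_subject():
    return synth.make_healthy_subject(1)


@pytest.fixture(scope="session")
def healthy_session(healthy_subject):
    """One full healthy-protocol session (60 trials)."""
    return synth.simulate_session(healthy_subject, synth.healthy_protocol())


@pytest.fixture(scope="session")
def healthy_windows(healthy_session):
    """Filtered [-100, 100] ms analysis windows of the healthy session."""
    return preprocess.window_session(healthy_session)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
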