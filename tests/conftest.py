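import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import smpipe as sp

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def config() -> sp.PipelineConfig:
    return sp.PipelineConfig()


@pytest.fixture
def key() -> sp.SessionKey:
    return sp.SessionKey(student_id="S1", session_id="sess01")


@pytest.fixture
def flat_series(key) -> sp.HRSeries:
    """600 s of constant 70 bpm at 1 Hz: one coverage interval, no dynamics."""
    t = np.arange(600.0)
    return sp.HRSeries.from_samples(key, t, np.full(600, 70.0))


@pytest.fixture(scope="session")
def small_cohort():
    """One student, two sessions, default episode conditions."""
    cfg = sp.SyntheticConfig(n_students=1, n_sessions=2, seed=3)
    return sp.generate_cohort(cfg)
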