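import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import renalflow as rf
from renalflow import waveform_synth as ws

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """20 synthetic patients (40 signals), default separable regimes."""
    return ws.generate_cohort(20, seed=123)


@pytest.fixture(scope="session")
def small_datasheet(small_cohort):
    return rf.Datasheet.from_signals(ws.cohort_signals(small_cohort))


@pytest.fixture(scope="session")
def toy_training_set():
    """64 signals (32 per class) from widely separated regimes."""
    cohort = ws.generate_cohort(32, seed=7)
    ds = rf.Datasheet.from_signals(ws.cohort_signals(cohort))
    return ds.velocities(), ds.labels01()
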