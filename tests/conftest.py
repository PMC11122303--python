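import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import damkit as dk

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def plain_params():
    """A strain without fly-level random effects or circadian sleep gating,
    so closed-form expectations for the two-state chain are exact."""
    return dk.StrainParams(
        name="plain", mesor=1.0, morning_peak_amp=2.0, evening_peak_amp=3.0,
        sleep_pressure=0.01, mean_bout_min=30.0,
        cv_activity=0.0, peak_jitter_h=0.0, cv_sleep=0.0,
        sleep_circadian_coupling=0.0,
    )


@pytest.fixture
def ld_config():
    return dk.SimConfig(n_days=2, seed=1234)


def make_trace(counts, missing=None, **kwargs):
    return dk.MinuteTrace(fly_id=kwargs.pop("fly_id", "fly"), counts=counts,
                          missing=missing, **kwargs)
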