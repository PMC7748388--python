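import math

import pytest
from hypothesis import HealthCheck, settings

from colidose import DosingModelConfig

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def identity_model():
    """Synthetic config with f(CrCl) = CrCl, forcing baseline = css * CrCl."""
    return DosingModelConfig(
        name="identity",
        bands=((0.0, 0.0), (1000.0, 1000.0)),
        interpolate=True,
    )


@pytest.fixture
def step_model():
    """Small step-band config: <30 -> 100, <90 -> 200, >=90 -> 300 mg/day per mg/L."""
    return DosingModelConfig(
        name="steps",
        bands=((30.0, 100.0), (90.0, 200.0), (math.inf, 300.0)),
    )


@pytest.fixture
def store_path(tmp_path):
    return tmp_path / "history.jsonl"
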