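import numpy as np
import pytest

from hapticsway.model_core import (
    BodyParams,
    ConflictParams,
    ControlParams,
    GainCondition,
    ModelConfig,
    NoiseParams,
)


@pytest.fixture(scope="session")
def body():
    return BodyParams()


@pytest.fixture(scope="session")
def ctrl():
    return ControlParams()


@pytest.fixture(scope="session")
def default_config():
    return ModelConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quiet_trace(body, ctrl):
    """One 410-s default-parameter run at G=0, decimated to 120 Hz."""
    from hapticsway.model_core import simulate_trial

    return simulate_trial(
        body,
        ctrl,
        ConflictParams(),
        NoiseParams(seed=11),
        GainCondition(0.0),
        410.0,
        keep_every=10,
        discard_s=10.0,
    )
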