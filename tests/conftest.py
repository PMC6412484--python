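import numpy as np
import pytest

import fogsense as fg
from fogsense.signal_model import Channel, Muscle, Side


@pytest.fixture
def cfg():
    return fg.PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_trace(values, fs=200.0, channel=Channel.GYRO_Z, side=Side.RIGHT,
               muscle=Muscle.TA, **kw):
    return fg.SignalTrace(values=np.asarray(values, dtype=float), fs=fs,
                          channel=channel, side=side, muscle=muscle, **kw)


@pytest.fixture
def tug_session():
    """One deterministic TUG-like synthetic session (seed 7)."""
    return fg.generate_session(fg.default_tug_script(7))


@pytest.fixture(scope="session")
def tug_sessions():
    """Ten seeded TUG-like sessions, shared across tests (read-only)."""
    return [fg.generate_session(fg.default_tug_script(seed))
            for seed in range(10)]
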