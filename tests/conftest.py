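import numpy as np
import pytest

from emgforce.preprocess import preprocess_recording
from emgforce.presets import demo_preprocess_kwargs
from emgforce.simulate import (
    EmgGenConfig,
    Matching,
    ProtocolConfig,
    TaskSpec,
    generate_recording,
)


def tiny_protocol(n_tasks: int = 2, n_periods: int = 3, fs: float = 2048.0) -> ProtocolConfig:
    """Two-channel, 30 s-per-task protocol small enough for unit tests."""
    tasks = tuple(TaskSpec(str(i + 1), i) for i in range(n_tasks))
    matchings = tuple(Matching(i, i, +1) for i in range(n_tasks))
    return ProtocolConfig(
        n_emg_channels=n_tasks,
        n_force_channels=n_tasks,
        fs=fs,
        sine_freq=0.1,
        n_periods=n_periods,
        mvc_fraction=0.2,
        mvc_level=1.0,
        tasks=tasks,
        matchings=matchings,
    )


def tiny_gen(seed: int = 0, **kw) -> EmgGenConfig:
    defaults = dict(
        crosstalk=None,
        nonlinearity_exponent=1.0,
        carrier_band=(20.0, 100.0),
        noise_floor_sd=0.0,
        tracking_error_sd=0.0,
        seed=seed,
    )
    defaults.update(kw)
    return EmgGenConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_recording():
    return generate_recording(tiny_protocol(), tiny_gen(seed=7))


@pytest.fixture(scope="session")
def tiny_windows(tiny_recording):
    """Preprocessed WindowSet of the tiny recording (256 Hz, 64-sample windows)."""
    return preprocess_recording(tiny_recording, **demo_preprocess_kwargs())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
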