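"""Ready-made configurations.

``study_*`` mirror the full acquisition protocol (6 iEMG channels, 9 force
gauges, 10240 Hz, 8 tasks x 10 periods of a 0.1 Hz sinusoid at 20 % MVC,
512-sample windows at 1024 Hz).  ``demo_*`` is the desk-scale benchmark the
test suite and worked examples use: the same pipeline end to end, but sized
to run on a laptop CPU in minutes — 4 tasks x 5 periods at 2048 Hz with 4
EMG channels matched one-to-one to the 4 task DoFs, decimation to 256 Hz,
250 ms windows, and narrower networks trained with a larger learning rate
for a handful of epochs.  Off-diagonal crosstalk 0.3 and a nonlinear
(alpha = 1.6) force-to-amplitude map put the demo in the regime where the
linear baseline is handicapped and cross-channel context matters.
"""

from __future__ import annotations

import numpy as np

from .architecture import ArchitectureSpec
from .preprocess import FilterSpec, WindowConfig
from .simulate import EmgGenConfig, Matching, ProtocolConfig, TaskSpec
from .training import TrainConfig

__all__ = [
    "study_protocol",
    "study_gen",
    "demo_protocol",
    "demo_gen",
    "demo_arch",
    "demo_train_config",
    "demo_preprocess_kwargs",
]


def study_protocol() -> ProtocolConfig:
    """Full-scale protocol geometry (about 13 min of 10.24 kHz data)."""
    return ProtocolConfig()


def study_gen(seed: int = 0) -> EmgGenConfig:
    return EmgGenConfig(
        crosstalk=None,  # identity
        nonlinearity_exponent=1.0,
        carrier_band=(20.0, 500.0),
        noise_floor_sd=0.05,
        tracking_error_sd=0.2,
        seed=seed,
    )


def demo_protocol(n_tasks: int = 4, n_periods: int = 5, fs: float = 2048.0) -> ProtocolConfig:
    tasks = tuple(
        TaskSpec(code=str(i + 1), force_channel=i, description=f"DoF {i}")
        for i in range(n_tasks)
    )
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


def demo_gen(seed: int = 0, crosstalk_offdiag: float = 0.3, alpha: float = 1.6,
             n_channels: int = 4) -> EmgGenConfig:
    ct = np.full((n_channels, n_channels), crosstalk_offdiag)
    np.fill_diagonal(ct, 1.0)
    return EmgGenConfig(
        crosstalk=ct,
        nonlinearity_exponent=alpha,
        carrier_band=(20.0, 100.0),
        noise_floor_sd=0.1,
        tracking_error_sd=0.01,
        seed=seed,
    )


def demo_preprocess_kwargs() -> dict:
    """Preprocessing settings matched to the 2048 Hz demo protocol.

    The EMG low-pass sits at 100 Hz so that decimation by 8 (to 256 Hz,
    Nyquist 128 Hz) remains alias-free; windows are 64 samples (250 ms)
    with step 64.
    """
    return dict(
        emg_filter=FilterSpec(cutoff_hz=100.0),
        force_filter=FilterSpec(cutoff_hz=10.0),
        decimation=8,
        window=WindowConfig(width_samples=64, step_samples=64),
    )


def demo_arch() -> ArchitectureSpec:
    """Narrow network for the desk-scale benchmark (same topology)."""
    return ArchitectureSpec(
        window_len=64,
        conv_filters=32,
        conv_kernel=21,
        lstm_units=32,
        fc1_units=16,
    )


def demo_train_config(seed: int = 0, max_epochs: int = 30) -> TrainConfig:
    return TrainConfig(
        learning_rate=5e-3,
        batch_size=32,
        patience_epochs=max_epochs,
        max_epochs=max_epochs,
        seed=seed,
    )
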