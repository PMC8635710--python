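"""The three regression strategies and exact parameter accounting.

One-to-One: one network per force channel, fed its single paired iEMG
channel.  All-to-One: one network per force channel, fed all iEMG channels.
All-to-All: a single network fed all channels, emitting all forces at once.
The architectures are identical except for the convolution's input width and
the final fully connected layer's output width.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

__all__ = ["StrategyKind", "ArchitectureSpec", "build_model", "count_parameters"]


class StrategyKind(str, Enum):
    ONE_TO_ONE = "one_to_one"
    ALL_TO_ONE = "all_to_one"
    ALL_TO_ALL = "all_to_all"


@dataclass(frozen=True)
class ArchitectureSpec:
    """Conv1D + LSTM + 2 FC regression network.

    Layer order: Conv1D (same-padded, unit stride) -> leaky ReLU -> layer
    norm -> dropout -> LSTM (final-time-step output) -> leaky ReLU -> layer
    norm -> dropout -> FC (hidden) -> leaky ReLU -> dropout -> FC (linear).
    """

    window_len: int = 512
    in_channels: int = 1
    conv_filters: int = 64
    conv_kernel: int = 21
    lstm_units: int = 64
    fc1_units: int = 32
    out_units: int = 1
    leaky_relu_slope: float = 0.2
    dropout_p: float = 0.2


def build_model(
    strategy: StrategyKind,
    n_emg_channels: int = 6,
    base: ArchitectureSpec = ArchitectureSpec(),
) -> ArchitectureSpec:
    """Architecture for a strategy; only conv input and head width vary."""
    strategy = StrategyKind(strategy)
    if strategy is StrategyKind.ONE_TO_ONE:
        return replace(base, in_channels=1, out_units=1)
    if strategy is StrategyKind.ALL_TO_ONE:
        return replace(base, in_channels=n_emg_channels, out_units=1)
    return replace(base, in_channels=n_emg_channels, out_units=n_emg_channels)


def count_parameters(spec: ArchitectureSpec) -> int:
    """Closed-form learnable-parameter count.

    conv: kernel*in*filters + filters; layer norm after conv: 2*filters;
    LSTM: 4*(units*(units + input) + units); layer norm after LSTM: 2*units;
    FC1: lstm*fc1 + fc1; FC2: fc1*out + out.
    """
    conv = spec.conv_kernel * spec.in_channels * spec.conv_filters + spec.conv_filters
    ln1 = 2 * spec.conv_filters
    lstm = 4 * (spec.lstm_units * (spec.lstm_units + spec.conv_filters) + spec.lstm_units)
    ln2 = 2 * spec.lstm_units
    fc1 = spec.lstm_units * spec.fc1_units + spec.fc1_units
    fc2 = spec.fc1_units * spec.out_units + spec.out_units
    return conv + ln1 + lstm + ln2 + fc1 + fc2
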