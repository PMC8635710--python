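"""Synthetic iEMG/force recordings emulating an isometric sine-tracking protocol.

The generator reproduces the statistical structure of a multichannel
intramuscular-EMG acquisition session: a subject tracks a low-frequency
(0.1 Hz) sinusoidal force target at 20 % of maximum voluntary contraction
(MVC), one degree of freedom (DoF) at a time, while six fine-wire EMG
channels and nine force gauges are sampled synchronously.

The surrogate EMG model is amplitude-modulated band-limited noise: each EMG
channel carries a carrier of interference-pattern noise whose instantaneous
amplitude follows a (possibly nonlinear) function of the phase-specific
force envelope of its source muscle, plus configurable crosstalk from the
other sources and an additive noise floor.  This is not a physiological
motor-unit simulation; it preserves exactly the properties downstream
regression exploits (envelope coding, spectral band, channel mixing).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "TaskSpec",
    "Matching",
    "ProtocolConfig",
    "EmgGenConfig",
    "RawRecording",
    "Segment",
    "generate_force_profile",
    "generate_emg",
    "generate_recording",
]


@dataclass(frozen=True)
class TaskSpec:
    """A single-DoF sine-tracking task.

    ``force_channel`` is the gauge actuated by the task; both movement
    phases of the DoF (e.g. flexion and extension) are exercised by the
    positive and negative half-cycles of the tracking cue.
    """

    code: str
    force_channel: int
    description: str = ""


@dataclass(frozen=True)
class Matching:
    """EMG channel -> (force channel, phase sign) pairing.

    ``phase_sign`` is +1 if the muscle drives the positive cue phase
    (flexion / adduction / pronation), -1 for the antagonist phase.
    """

    emg_channel: int
    force_channel: int
    phase_sign: int = 1

    def __post_init__(self) -> None:
        if self.phase_sign not in (-1, 1):
            raise ValueError(f"phase_sign must be +1 or -1, got {self.phase_sign}")


def _default_tasks() -> tuple[TaskSpec, ...]:
    names = [
        "index flexion-extension",
        "middle flexion-extension",
        "ring flexion-extension",
        "little flexion-extension",
        "thumb flexion-extension",
        "thumb adduction-abduction",
        "wrist flexion-extension",
        "wrist supination-pronation",
    ]
    return tuple(
        TaskSpec(code=str(i + 1), force_channel=i, description=n)
        for i, n in enumerate(names)
    )


def _default_matchings() -> tuple[Matching, ...]:
    # Six forearm muscles, each matched to one phase-specific force channel.
    return (
        Matching(0, 6, +1),  # FCR -> wrist flexion
        Matching(1, 6, -1),  # ECR -> wrist extension
        Matching(2, 7, +1),  # PT  -> pronation
        Matching(3, 0, +1),  # FDP -> index flexion
        Matching(4, 1, -1),  # EDC -> middle extension
        Matching(5, 5, -1),  # APL -> thumb abduction
    )


@dataclass(frozen=True)
class ProtocolConfig:
    """Acquisition-protocol geometry: channel counts, rates, task list."""

    n_emg_channels: int = 6
    n_force_channels: int = 9
    fs: float = 10240.0
    sine_freq: float = 0.1
    n_periods: int = 10
    mvc_fraction: float = 0.2
    mvc_level: float = 50.0
    tasks: tuple[TaskSpec, ...] = field(default_factory=_default_tasks)
    matchings: tuple[Matching, ...] = field(default_factory=_default_matchings)

    def __post_init__(self) -> None:
        if self.sine_freq <= 0:
            raise ValueError("sine_freq must be positive")
        if self.n_periods < 3:
            raise ValueError("n_periods must be >= 3 to cover a train/val/test split")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for t in self.tasks:
            if not 0 <= t.force_channel < self.n_force_channels:
                raise ValueError(
                    f"task {t.code!r} references force channel {t.force_channel}, "
                    f"but only {self.n_force_channels} exist"
                )
        for m in self.matchings:
            if not 0 <= m.emg_channel < self.n_emg_channels:
                raise ValueError(f"matching references EMG channel {m.emg_channel}")
            if not 0 <= m.force_channel < self.n_force_channels:
                raise ValueError(f"matching references force channel {m.force_channel}")

    @property
    def task_duration_s(self) -> float:
        return self.n_periods / self.sine_freq

    @property
    def samples_per_task(self) -> int:
        return int(round(self.task_duration_s * self.fs))

    @property
    def samples_per_period(self) -> float:
        return self.fs / self.sine_freq

    @property
    def total_samples(self) -> int:
        return self.samples_per_task * len(self.tasks)


@dataclass(frozen=True)
class EmgGenConfig:
    """Parameters of the amplitude-modulation EMG surrogate.

    crosstalk[k, j] is the gain with which source envelope j (the
    phase-specific force envelope of matching j) modulates EMG channel k.
    The diagonal carries each channel's own muscle; off-diagonal entries
    emulate mechanical/electrical crosstalk.  ``nonlinearity_exponent``
    is the alpha of the monotone force->amplitude map a = (f/f_ref)^alpha.
    """

    crosstalk: np.ndarray | None = None
    nonlinearity_exponent: float = 1.0
    carrier_band: tuple[float, float] = (20.0, 500.0)
    noise_floor_sd: float = 0.0
    tracking_error_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.carrier_band
        if not 0 < lo < hi:
            raise ValueError("carrier_band must satisfy 0 < low < high")
        if self.noise_floor_sd < 0 or self.tracking_error_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.crosstalk is not None:
            ct = np.asarray(self.crosstalk, dtype=float)
            if ct.ndim != 2:
                raise ValueError("crosstalk must be a 2-D matrix")
            if (ct < 0).any():
                raise ValueError("crosstalk gains must be nonnegative")
            if (np.diagonal(ct) <= 0).any():
                raise ValueError("crosstalk diagonal must be positive")
            object.__setattr__(self, "crosstalk", ct)


@dataclass(frozen=True)
class Segment:
    """Half-open sample range [start, stop) of one sinusoid period of a task."""

    start: int
    stop: int
    task_code: str
    period: int  # 1-based period index within the task


@dataclass
class RawRecording:
    """Sample-synchronized raw session: EMG, force, cue, and annotations."""

    emg: np.ndarray  # (T, K_e)
    force: np.ndarray  # (T, K_f)
    cue: np.ndarray  # (T, K_f), signed tracking cue
    task_segments: list[Segment]
    matchings: tuple[Matching, ...]
    fs: float
    emg_names: tuple[str, ...] = ()
    force_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        T = self.emg.shape[0]
        if self.force.shape[0] != T or self.cue.shape[0] != T:
            raise ValueError("emg, force and cue must share their row count")
        if self.cue.shape[1] != self.force.shape[1]:
            raise ValueError("cue must have one column per force channel")
        for m in self.matchings:
            if not 0 <= m.emg_channel < self.emg.shape[1]:
                raise ValueError(f"matching references EMG channel {m.emg_channel}")
            if not 0 <= m.force_channel < self.force.shape[1]:
                raise ValueError(f"matching references force channel {m.force_channel}")
        prev = 0
        for s in self.task_segments:
            if s.start < prev or s.stop <= s.start or s.stop > T:
                raise ValueError("task segments must be disjoint, ordered and in range")
            prev = s.stop

    @property
    def n_samples(self) -> int:
        return self.emg.shape[0]


def _smooth_noise(rng: np.random.Generator, n: int, sd: float, fs: float,
                  cutoff_hz: float = 1.0) -> np.ndarray:
    """White noise low-passed at ``cutoff_hz`` and rescaled to SD ``sd``."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    b, a = signal.butter(2, cutoff_hz / (fs / 2.0), btype="low")
    x = signal.lfilter(b, a, w)
    s = x.std()
    if s > 0:
        x *= sd / s
    return x


def _band_noise(rng: np.random.Generator, n: int, band: tuple[float, float],
                fs: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to ``band``.

    A steep (order-10) Butterworth in second-order sections keeps the
    out-of-band power of the carrier below a few percent of the total.
    """
    w = rng.standard_normal(n)
    lo, hi = band
    nyq = fs / 2.0
    if hi >= nyq:
        raise ValueError(f"carrier band upper edge {hi} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(10, [lo / nyq, hi / nyq], btype="band", output="sos")
    x = signal.sosfilt(sos, w)
    s = x.std()
    if s > 0:
        x /= s
    return x


def generate_force_profile(
    protocol: ProtocolConfig,
    task: TaskSpec,
    gen: EmgGenConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Force and cue traces for one sine-tracking task.

    Returns ``(force, cue, period_bounds)`` where ``force`` and ``cue`` are
    (T, n_force_channels) and ``period_bounds`` holds the n_periods + 1
    sample offsets delimiting full cue cycles.  The active channel tracks
    target(t) = mvc_fraction * mvc_level * |sin(2 pi f t)| with smooth
    (<= 1 Hz) tracking error; inactive channels carry tracking noise only.
    """
    if task.force_channel >= protocol.n_force_channels:
        raise ValueError(
            f"task {task.code!r} references force channel {task.force_channel} "
            f"of {protocol.n_force_channels}"
        )
    if rng is None:
        rng = np.random.default_rng(gen.seed)
    T = protocol.samples_per_task
    K = protocol.n_force_channels
    t = np.arange(T) / protocol.fs
    amp = protocol.mvc_fraction * protocol.mvc_level
    s = np.sin(2.0 * np.pi * protocol.sine_freq * t)

    cue = np.zeros((T, K))
    cue[:, task.force_channel] = amp * s

    force = np.empty((T, K))
    for k in range(K):
        force[:, k] = _smooth_noise(rng, T, gen.tracking_error_sd, protocol.fs)
    force[:, task.force_channel] += amp * np.abs(s)

    bounds = [int(round(i * protocol.samples_per_period)) for i in range(protocol.n_periods)]
    bounds.append(T)
    return force, cue, bounds


def _source_envelopes(force: np.ndarray, cue: np.ndarray,
                      matchings: tuple[Matching, ...]) -> np.ndarray:
    """Phase-specific rectified force envelope for each matching (T, n_matchings)."""
    env = np.zeros((force.shape[0], len(matchings)))
    for j, m in enumerate(matchings):
        gate = np.sign(cue[:, m.force_channel]) == m.phase_sign
        env[:, j] = np.where(gate, np.abs(force[:, m.force_channel]), 0.0)
    return env


def generate_emg(
    force: np.ndarray,
    cue: np.ndarray,
    matchings: tuple[Matching, ...],
    gen: EmgGenConfig,
    protocol: ProtocolConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Amplitude-modulated surrogate EMG (T, n_emg_channels).

    Channel k is sum_j crosstalk[k, j] * (env_j / f_ref)^alpha * n_kj(t)
    plus ``noise_floor_sd`` * w_k(t), with n_kj and w_k independent
    unit-variance noises band-limited to the carrier band, env_j the
    phase-specific envelope of matching j and f_ref = mvc_fraction * mvc_level.
    """
    if rng is None:
        rng = np.random.default_rng(gen.seed)
    K_e = protocol.n_emg_channels
    ct = gen.crosstalk
    if ct is None:
        ct = np.eye(K_e, len(matchings))
    if ct.shape != (K_e, len(matchings)):
        raise ValueError(
            f"crosstalk must be ({K_e}, {len(matchings)}), got {ct.shape}"
        )
    env = _source_envelopes(force, cue, matchings)
    f_ref = protocol.mvc_fraction * protocol.mvc_level
    alpha = gen.nonlinearity_exponent
    T = force.shape[0]
    emg = np.zeros((T, K_e))
    amps = (env / f_ref) ** alpha
    for k in range(K_e):
        for j in range(len(matchings)):
            if ct[k, j] == 0.0:
                continue
            emg[:, k] += ct[k, j] * amps[:, j] * _band_noise(
                rng, T, gen.carrier_band, protocol.fs
            )
        if gen.noise_floor_sd > 0:
            emg[:, k] += gen.noise_floor_sd * _band_noise(
                rng, T, gen.carrier_band, protocol.fs
            )
    return emg


def generate_recording(protocol: ProtocolConfig, gen: EmgGenConfig) -> RawRecording:
    """Full synthetic session: all tasks in order, one segment per period.

    Deterministic: identical (protocol, gen) including ``gen.seed`` gives a
    bit-identical recording.
    """
    rng = np.random.default_rng(gen.seed)
    forces, cues, segments = [], [], []
    offset = 0
    for task in protocol.tasks:
        f, c, bounds = generate_force_profile(protocol, task, gen, rng)
        forces.append(f)
        cues.append(c)
        for p in range(protocol.n_periods):
            segments.append(
                Segment(
                    start=offset + bounds[p],
                    stop=offset + bounds[p + 1],
                    task_code=task.code,
                    period=p + 1,
                )
            )
        offset += f.shape[0]
    force = np.concatenate(forces, axis=0)
    cue = np.concatenate(cues, axis=0)
    emg = generate_emg(force, cue, protocol.matchings, gen, protocol, rng)
    emg_names = tuple(f"emg{k}" for k in range(protocol.n_emg_channels))
    force_names = tuple(f"force{k}" for k in range(protocol.n_force_channels))
    return RawRecording(
        emg=emg,
        force=force,
        cue=cue,
        task_segments=segments,
        matchings=protocol.matchings,
        fs=protocol.fs,
        emg_names=emg_names,
        force_names=force_names,
    )


def with_seed(gen: EmgGenConfig, seed: int) -> EmgGenConfig:
    """Copy of ``gen`` with a different RNG seed."""
    return replace(gen, seed=seed)
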