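"""Causal preprocessing: clip, filter, decimate, phase-split, pair, window, split, normalize.

Every stage is executable online: filters are single-pass (causal) IIR, the
percentile clipping bounds and the normalization statistics are estimated on
the training portion only and then applied unchanged, and each sliding
window's regression target is the force at the window's *last* sample.

The chain, in order:

    clip -> low-pass (EMG 500 Hz, force 10 Hz) -> decimate -> phase-split /
    rectify -> pair EMG with matched force channels -> sliding windows ->
    period-based train/val/test split -> z-score (EMG) / unit-variance (force)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .simulate import Matching, RawRecording

__all__ = [
    "FilterSpec",
    "WindowConfig",
    "PairedSignals",
    "NormStats",
    "WindowSet",
    "clip_percentiles",
    "lowpass_filter",
    "decimate",
    "split_force_phases",
    "pair_and_select",
    "segment_windows",
    "split_by_period",
    "normalize",
    "preprocess_recording",
    "default_period_split",
]

logger = logging.getLogger(__name__)

TRAIN, VAL, TEST = 0, 1, 2
SPLIT_NAMES = ("train", "val", "test")


@dataclass(frozen=True)
class FilterSpec:
    """Causal Butterworth low-pass: order 2, cutoff 500 Hz (EMG) or 10 Hz (force)."""

    cutoff_hz: float
    order: int = 2

    def coefficients(self, fs: float) -> tuple[np.ndarray, np.ndarray]:
        if not 0 < self.cutoff_hz < fs / 2:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must lie in (0, {fs / 2}) for fs={fs}"
            )
        return signal.butter(self.order, self.cutoff_hz / (fs / 2.0), btype="low")


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry: 512 samples (500 ms at 1024 Hz), step 64 (62.5 ms)."""

    width_samples: int = 512
    step_samples: int = 64

    def __post_init__(self) -> None:
        if not self.width_samples >= self.step_samples >= 1:
            raise ValueError("need width_samples >= step_samples >= 1")


@dataclass
class PairedSignals:
    """Synchronous matrices E (iEMG) and F (phase-specific rectified force).

    Rows are index-aligned time samples that survived task selection;
    column c of F is the force envelope matched to EMG column c.
    ``sample_index`` keeps the pre-selection sample offsets so windowing can
    detect discontinuities introduced by discarding unmatched tasks.
    """

    E: np.ndarray  # (T, K)
    F: np.ndarray  # (T, K), >= 0
    task_code: np.ndarray  # (T,) str
    period_index: np.ndarray  # (T,) int, 1-based per task
    sample_index: np.ndarray  # (T,) int, offsets into the decimated stream
    fs: float
    matchings: tuple[Matching, ...] = ()

    def __post_init__(self) -> None:
        if self.E.shape != self.F.shape:
            raise ValueError("E and F must have identical shape")
        if (self.F < 0).any():
            raise ValueError("F must be nonnegative (rectified)")


@dataclass
class NormStats:
    """Training-set statistics used for (and inverted from) normalization."""

    emg_mean: np.ndarray  # (K,)
    emg_sd: np.ndarray  # (K,)
    force_sd: np.ndarray  # (C,)

    def normalize_emg(self, X: np.ndarray) -> np.ndarray:
        return (X - self.emg_mean) / self.emg_sd

    def normalize_force(self, Y: np.ndarray) -> np.ndarray:
        return Y / self.force_sd

    def denormalize_force(self, Y: np.ndarray) -> np.ndarray:
        return Y * self.force_sd


@dataclass
class WindowSet:
    """Normalized regression instances: X (N, W, K) windows, Y (N, C) targets."""

    X: np.ndarray
    Y: np.ndarray
    split: np.ndarray  # (N,) int in {TRAIN, VAL, TEST}
    period: np.ndarray  # (N,) period index of each window's last sample
    stats: NormStats
    fs: float
    config: WindowConfig

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[2]

    def subset(self, which: int) -> tuple[np.ndarray, np.ndarray]:
        m = self.split == which
        return self.X[m], self.Y[m]


def clip_percentiles(
    x: np.ndarray,
    low_pct: float = 1.0,
    high_pct: float = 99.0,
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """Clip ``x`` into the [low_pct, high_pct] percentile range of ``reference``.

    Percentiles use the linear-interpolation convention.  ``reference``
    defaults to ``x`` itself; in the online pipeline it is the training
    portion of the channel.  Idempotent.
    """
    if low_pct >= high_pct:
        raise ValueError("low_pct must be < high_pct")
    ref = x if reference is None else reference
    if ref.size == 0:
        raise ValueError("clipping reference is empty")
    lo, hi = np.percentile(ref, [low_pct, high_pct])
    return np.clip(x, lo, hi)


def lowpass_filter(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Single-pass causal Butterworth low-pass along axis 0 (zero initial state)."""
    b, a = spec.coefficients(fs)
    return signal.lfilter(b, a, x, axis=0)


def decimate(x: np.ndarray, factor: int) -> np.ndarray:
    """Keep every ``factor``-th sample starting at index 0 (no extra filtering).

    The caller must have low-passed below the new Nyquist already.
    """
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    return x[::factor]


def split_force_phases(force: np.ndarray, cue: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a force trace into rectified positive- and negative-phase channels.

    positive = |force| where cue > 0 else 0; negative = |force| where cue < 0
    else 0.  Samples with cue == 0 contribute to neither.
    """
    if force.shape != cue.shape:
        raise ValueError("force and cue must have equal shape")
    a = np.abs(force)
    pos = np.where(cue > 0, a, 0.0)
    neg = np.where(cue < 0, a, 0.0)
    return pos, neg


def _annotations(rec: RawRecording) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (task_code, period) arrays at the recording's native rate."""
    T = rec.n_samples
    task = np.full(T, "", dtype=object)
    period = np.zeros(T, dtype=int)
    for s in rec.task_segments:
        task[s.start : s.stop] = s.task_code
        period[s.start : s.stop] = s.period
    return task, period


def pair_and_select(
    emg: np.ndarray,
    force: np.ndarray,
    cue: np.ndarray,
    matchings: tuple[Matching, ...],
    task_code: np.ndarray,
    period_index: np.ndarray,
    fs: float,
    task_channel_map: dict[str, int],
) -> PairedSignals:
    """Pair each EMG channel with its matched phase-specific force channel.

    Samples from tasks whose active force channel is matched by no EMG
    channel are discarded; so are force channels with no matching.  EMG
    channels without a matching are dropped with a warning.
    """
    if len(matchings) == 0:
        raise ValueError("no iEMG-force matchings: nothing to pair")
    per_emg: dict[int, Matching] = {}
    for m in matchings:
        if m.emg_channel in per_emg:
            raise ValueError(f"EMG channel {m.emg_channel} has multiple matchings")
        per_emg[m.emg_channel] = m
    for k in range(emg.shape[1]):
        if k not in per_emg:
            logger.warning("EMG channel %d has no matching; dropping it", k)

    order = sorted(per_emg)  # stable column order by EMG channel index
    cols_E, cols_F = [], []
    for k in order:
        m = per_emg[k]
        pos, neg = split_force_phases(force[:, m.force_channel], cue[:, m.force_channel])
        cols_E.append(emg[:, m.emg_channel])
        cols_F.append(pos if m.phase_sign > 0 else neg)
    E = np.column_stack(cols_E)
    F = np.column_stack(cols_F)

    matched_channels = {m.force_channel for m in per_emg.values()}
    kept_tasks = {t for t, ch in task_channel_map.items() if ch in matched_channels}
    dropped = sorted(set(task_channel_map) - kept_tasks)
    if dropped:
        logger.warning("discarding tasks with no matched channel: %s", dropped)
    keep = np.array([t in kept_tasks for t in task_code], dtype=bool)

    return PairedSignals(
        E=E[keep],
        F=F[keep],
        task_code=np.asarray(task_code, dtype=object)[keep],
        period_index=np.asarray(period_index)[keep],
        sample_index=np.flatnonzero(keep),
        fs=fs,
        matchings=tuple(per_emg[k] for k in order),
    )


def _contiguous_runs(paired: PairedSignals) -> list[tuple[int, int]]:
    """Half-open row ranges of contiguous same-task samples (no straddling)."""
    T = paired.E.shape[0]
    if T == 0:
        return []
    gap = np.flatnonzero(
        (np.diff(paired.sample_index) != 1)
        | (paired.task_code[1:] != paired.task_code[:-1])
    )
    starts = np.concatenate(([0], gap + 1))
    stops = np.concatenate((gap + 1, [T]))
    return list(zip(starts.tolist(), stops.tolist()))


def expected_window_count(segment_lengths: list[int], cfg: WindowConfig) -> int:
    """Closed-form window count: sum over segments of floor((L - W)/step) + 1."""
    n = 0
    for L in segment_lengths:
        if L >= cfg.width_samples:
            n += (L - cfg.width_samples) // cfg.step_samples + 1
    return n


def segment_windows(
    paired: PairedSignals, cfg: WindowConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cut sliding windows that never straddle task/discontinuity boundaries.

    Returns ``(X, Y, period)`` with X of shape (N, W, K), Y[n] = F at the last
    sample of window n, and period[n] the period index at that sample.
    """
    W, step = cfg.width_samples, cfg.step_samples
    xs, ys, ps = [], [], []
    for start, stop in _contiguous_runs(paired):
        L = stop - start
        if L < W:
            continue
        n_win = (L - W) // step + 1
        ends = start + W - 1 + step * np.arange(n_win)
        view = np.lib.stride_tricks.sliding_window_view(
            paired.E[start:stop], W, axis=0
        )  # (L-W+1, K, W)
        xs.append(np.ascontiguousarray(view[::step].transpose(0, 2, 1)))
        ys.append(paired.F[ends])
        ps.append(paired.period_index[ends])
    K = paired.E.shape[1]
    if not xs:
        return (
            np.empty((0, W, K)),
            np.empty((0, K)),
            np.empty((0,), dtype=int),
        )
    return np.concatenate(xs), np.concatenate(ys), np.concatenate(ps)


def default_period_split(n_periods: int = 10) -> dict[int, int]:
    """Period -> split mapping: first 7 of 10 train, 8th val, 9th-10th test.

    For other period counts the same 70/10/20 proportions are applied
    (at least one period each), e.g. 5 periods -> 3 train / 1 val / 1 test.
    """
    if n_periods < 3:
        raise ValueError("need at least 3 periods for a 3-way split")
    n_train = max(1, int(round(0.7 * n_periods)))
    n_val = max(1, int(round(0.1 * n_periods)))
    while n_train + n_val >= n_periods:
        n_train -= 1
    mapping = {}
    for p in range(1, n_periods + 1):
        if p <= n_train:
            mapping[p] = TRAIN
        elif p <= n_train + n_val:
            mapping[p] = VAL
        else:
            mapping[p] = TEST
    return mapping


def split_by_period(period: np.ndarray, mapping: dict[int, int]) -> np.ndarray:
    """Label each window train/val/test by the period of its last sample."""
    unknown = set(np.unique(period)) - set(mapping)
    if unknown:
        raise ValueError(f"periods {sorted(unknown)} not covered by the split mapping")
    return np.array([mapping[int(p)] for p in period], dtype=int)


def normalize(
    X: np.ndarray,
    Y: np.ndarray,
    split: np.ndarray,
    period: np.ndarray,
    fs: float,
    cfg: WindowConfig,
) -> WindowSet:
    """Rescale with training-split statistics.

    EMG: channel-wise z-score (mean and SD over all training-window samples).
    Force targets: channel-wise division by the training SD, no mean
    subtraction — the targets are rectified, so their mean is left intact.
    """
    train = split == TRAIN
    if not train.any():
        raise ValueError("training split is empty")
    Xt = X[train]
    emg_mean = Xt.mean(axis=(0, 1))
    emg_sd = Xt.std(axis=(0, 1))
    force_sd = Y[train].std(axis=0)
    for name, sd in (("EMG", emg_sd), ("force", force_sd)):
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(f"zero-variance {name} channel(s) {bad.tolist()} in training split")
    stats = NormStats(emg_mean=emg_mean, emg_sd=emg_sd, force_sd=force_sd)
    return WindowSet(
        X=stats.normalize_emg(X),
        Y=stats.normalize_force(Y),
        split=split,
        period=period,
        stats=stats,
        fs=fs,
        config=cfg,
    )


def preprocess_recording(
    rec: RawRecording,
    emg_filter: FilterSpec = FilterSpec(cutoff_hz=500.0),
    force_filter: FilterSpec = FilterSpec(cutoff_hz=10.0),
    decimation: int = 10,
    window: WindowConfig = WindowConfig(),
    period_split: dict[int, int] | None = None,
    clip_low_pct: float = 1.0,
    clip_high_pct: float = 99.0,
) -> WindowSet:
    """Full causal chain from a raw recording to a normalized WindowSet."""
    task, period = _annotations(rec)
    if period_split is None:
        n_periods = max(s.period for s in rec.task_segments)
        period_split = default_period_split(n_periods)
    train_periods = {p for p, s in period_split.items() if s == TRAIN}
    train_mask = np.isin(period, list(train_periods)) & (period > 0)

    emg = np.empty_like(rec.emg)
    for k in range(rec.emg.shape[1]):
        ref = rec.emg[train_mask, k]
        emg[:, k] = clip_percentiles(rec.emg[:, k], clip_low_pct, clip_high_pct, ref)
    emg = lowpass_filter(emg, emg_filter, rec.fs)
    force = lowpass_filter(rec.force, force_filter, rec.fs)

    emg_d = decimate(emg, decimation)
    force_d = decimate(force, decimation)
    cue_d = decimate(rec.cue, decimation)
    task_d = decimate(task, decimation)
    period_d = decimate(period, decimation)
    fs_d = rec.fs / decimation

    task_channel_map = {s.task_code: None for s in rec.task_segments}
    for s in rec.task_segments:
        task_channel_map[s.task_code] = _active_channel(rec, s)
    paired = pair_and_select(
        emg_d, force_d, cue_d, rec.matchings, task_d, period_d, fs_d,
        {t: ch for t, ch in task_channel_map.items() if ch is not None},
    )
    X, Y, win_period = segment_windows(paired, window)
    split = split_by_period(win_period, period_split)
    return normalize(X, Y, split, win_period, fs_d, window)


def _active_channel(rec: RawRecording, seg) -> int | None:
    """Force channel with the largest cue excursion during a segment."""
    c = np.abs(rec.cue[seg.start : seg.stop]).max(axis=0)
    if c.max() == 0:
        return None
    return int(np.argmax(c))
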