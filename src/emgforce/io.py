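"""Recording exchange format, WindowSet container, and run configuration.

A recording bundle is a directory of three CSV matrices (``emg.csv``,
``force.csv``, ``cue.csv``, one header row each) plus ``meta.json`` holding
the sampling rate, the iEMG-force matchings, and the task segments with
period indices.  CSV keeps the exchange layer diff-able and free of binary
dependencies; the (much larger) WindowSet goes into an HDF5 container with
a JSON sidecar for the normalization statistics and split counts.

An adapter for the original public database would map its session files
onto this bundle layout; the core pipeline only ever sees bundles.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .preprocess import NormStats, WindowConfig, WindowSet
from .simulate import Matching, RawRecording, Segment

__all__ = [
    "write_recording",
    "read_recording",
    "save_windows",
    "load_windows",
    "RunConfig",
    "BundleError",
]

_FLOAT_FMT = "%.17g"  # lossless float64 round trip


class BundleError(ValueError):
    """A recording bundle failed validation."""


def write_recording(rec: RawRecording, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    emg_names = rec.emg_names or tuple(f"emg{k}" for k in range(rec.emg.shape[1]))
    force_names = rec.force_names or tuple(f"force{k}" for k in range(rec.force.shape[1]))
    pd.DataFrame(rec.emg, columns=emg_names).to_csv(
        path / "emg.csv", index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame(rec.force, columns=force_names).to_csv(
        path / "force.csv", index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame(rec.cue, columns=force_names).to_csv(
        path / "cue.csv", index=False, float_format=_FLOAT_FMT
    )
    meta = {
        "fs": rec.fs,
        "matchings": [
            {"emg_channel": m.emg_channel, "force_channel": m.force_channel,
             "phase_sign": m.phase_sign}
            for m in rec.matchings
        ],
        "task_segments": [
            {"start": s.start, "stop": s.stop, "task_code": s.task_code,
             "period": s.period}
            for s in rec.task_segments
        ],
        "emg_names": list(emg_names),
        "force_names": list(force_names),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_recording(path: str | Path) -> RawRecording:
    path = Path(path)
    for f in ("emg.csv", "force.csv", "cue.csv", "meta.json"):
        if not (path / f).exists():
            raise BundleError(f"missing bundle file: {path / f}")
    try:
        meta = json.loads((path / "meta.json").read_text())
    except json.JSONDecodeError as err:
        raise BundleError(f"malformed meta.json: {err}") from err
    emg = pd.read_csv(path / "emg.csv").to_numpy(dtype=float)
    force = pd.read_csv(path / "force.csv").to_numpy(dtype=float)
    cue = pd.read_csv(path / "cue.csv").to_numpy(dtype=float)
    if not (emg.shape[0] == force.shape[0] == cue.shape[0]):
        raise BundleError(
            f"row-count mismatch: emg {emg.shape[0]}, force {force.shape[0]}, "
            f"cue {cue.shape[0]}"
        )
    if float(meta.get("fs", 0)) <= 0:
        raise BundleError("meta.json must declare a positive fs")
    matchings = tuple(
        Matching(m["emg_channel"], m["force_channel"], m.get("phase_sign", 1))
        for m in meta.get("matchings", [])
    )
    for m in matchings:
        if m.emg_channel >= emg.shape[1] or m.force_channel >= force.shape[1]:
            raise BundleError(
                f"matching {m} references a column outside the data "
                f"({emg.shape[1]} EMG / {force.shape[1]} force channels)"
            )
    segments = [
        Segment(s["start"], s["stop"], str(s["task_code"]), s["period"])
        for s in meta.get("task_segments", [])
    ]
    try:
        return RawRecording(
            emg=emg, force=force, cue=cue, task_segments=segments,
            matchings=matchings, fs=float(meta["fs"]),
            emg_names=tuple(meta.get("emg_names", [])),
            force_names=tuple(meta.get("force_names", [])),
        )
    except ValueError as err:
        raise BundleError(str(err)) from err


def save_windows(ws: WindowSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=ws.X, compression="gzip")
        f.create_dataset("Y", data=ws.Y)
        f.create_dataset("split", data=ws.split)
        f.create_dataset("period", data=ws.period)
        f.attrs["fs"] = ws.fs
        f.attrs["width_samples"] = ws.config.width_samples
        f.attrs["step_samples"] = ws.config.step_samples
        g = f.create_group("stats")
        g.create_dataset("emg_mean", data=ws.stats.emg_mean)
        g.create_dataset("emg_sd", data=ws.stats.emg_sd)
        g.create_dataset("force_sd", data=ws.stats.force_sd)
    sidecar = {
        "fs": ws.fs,
        "n_windows": int(ws.n_windows),
        "n_channels": int(ws.n_channels),
        "split_counts": {
            name: int((ws.split == i).sum())
            for i, name in enumerate(("train", "val", "test"))
        },
        "emg_mean": ws.stats.emg_mean.tolist(),
        "emg_sd": ws.stats.emg_sd.tolist(),
        "force_sd": ws.stats.force_sd.tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_windows(path: str | Path) -> WindowSet:
    with h5py.File(path, "r") as f:
        return WindowSet(
            X=f["X"][()],
            Y=f["Y"][()],
            split=f["split"][()],
            period=f["period"][()],
            stats=NormStats(
                emg_mean=f["stats/emg_mean"][()],
                emg_sd=f["stats/emg_sd"][()],
                force_sd=f["stats/force_sd"][()],
            ),
            fs=float(f.attrs["fs"]),
            config=WindowConfig(
                width_samples=int(f.attrs["width_samples"]),
                step_samples=int(f.attrs["step_samples"]),
            ),
        )


class RunConfig(BaseModel):
    """Validated end-to-end run configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    n_recordings: int = Field(default=3, ge=1)
    n_tasks: int = Field(default=4, ge=1)
    n_periods: int = Field(default=5, ge=3)
    fs: float = Field(default=2048.0, gt=0)
    crosstalk_offdiag: float = Field(default=0.3, ge=0)
    nonlinearity_exponent: float = 1.6
    emg_cutoff_hz: float = Field(default=100.0, gt=0)
    force_cutoff_hz: float = Field(default=10.0, gt=0)
    decimation: int = Field(default=8, ge=1)
    window_width: int = Field(default=64, ge=1)
    window_step: int = Field(default=64, ge=1)
    conv_filters: int = Field(default=32, ge=1)
    lstm_units: int = Field(default=32, ge=1)
    fc1_units: int = Field(default=16, ge=1)
    learning_rate: float = Field(default=2e-3, gt=0)
    max_epochs: int = Field(default=10, ge=1)
    patience_epochs: int = Field(default=10, ge=1)
    strategies: list[str] = Field(
        default_factory=lambda: ["linear", "one_to_one", "all_to_one", "all_to_all"]
    )
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())
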