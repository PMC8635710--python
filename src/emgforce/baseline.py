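"""Status-quo comparator: mean-absolute-value feature + univariate OLS.

For each iEMG/force channel pair, the MAV of the (normalized) iEMG window
is the single predictor of the concurrent force target, fitted by ordinary
least squares.  Each model therefore has exactly two parameters: slope and
intercept.  Predictions are not clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import TRAIN, WindowSet

__all__ = ["LinearModel", "mav", "fit_linear", "predict_linear", "fit_baseline"]


@dataclass(frozen=True)
class LinearModel:
    """force = slope * MAV(emg window) + intercept, for one channel pair."""

    slope: float
    intercept: float
    emg_channel: int
    force_channel: int

    @property
    def n_parameters(self) -> int:
        return 2

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("linear model coefficients must be finite")


def mav(window: np.ndarray) -> float | np.ndarray:
    """Mean absolute value over the window axis.

    Accepts a single window (W,) or a stack (N, W) / (N, W, K); the mean is
    always taken over the time axis.
    """
    w = np.asarray(window)
    if w.size == 0:
        raise ValueError("MAV of an empty window is undefined")
    axis = 0 if w.ndim == 1 else 1
    return np.abs(w).mean(axis=axis)


def fit_linear(
    mav_values: np.ndarray, targets: np.ndarray, emg_channel: int = 0,
    force_channel: int = 0,
) -> LinearModel:
    """Closed-form univariate OLS of targets on MAV (normal equations)."""
    x = np.asarray(mav_values, dtype=float)
    y = np.asarray(targets, dtype=float)
    if x.ndim != 1 or x.shape != y.shape or x.size < 2:
        raise ValueError("need >= 2 paired (MAV, target) training instances")
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        raise ValueError(
            f"constant MAV on channel {emg_channel}: singular design matrix"
        )
    slope = np.sum((x - xm) * (y - ym)) / sxx
    return LinearModel(
        slope=float(slope),
        intercept=float(ym - slope * xm),
        emg_channel=emg_channel,
        force_channel=force_channel,
    )


def predict_linear(models: list[LinearModel], X: np.ndarray) -> np.ndarray:
    """Per-channel predictions (N, C) from windows (N, W, K).

    ``models[c]`` must cover force channel c; its ``emg_channel`` selects the
    iEMG column whose MAV drives the prediction.
    """
    if X.ndim != 3:
        raise ValueError(f"expected windows (N, W, K), got shape {X.shape}")
    N = X.shape[0]
    out = np.empty((N, len(models)))
    for c, m in enumerate(models):
        if m is None:
            raise ValueError(f"missing linear model for force channel {c}")
        feats = mav(X[:, :, m.emg_channel]) if N else np.empty(0)
        out[:, c] = m.slope * feats + m.intercept
    return out


def fit_baseline(windows: WindowSet) -> list[LinearModel]:
    """One univariate model per paired channel, fitted on the training split."""
    Xtr, Ytr = windows.subset(TRAIN)
    return [
        fit_linear(mav(Xtr[:, :, c]), Ytr[:, c], emg_channel=c, force_channel=c)
        for c in range(windows.n_channels)
    ]
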