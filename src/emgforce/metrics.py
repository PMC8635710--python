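"""Regression metrics: normalized RMSE and variance accounted for (VAF).

Both metrics summarize one method on one recording session.  RMSE here is
the per-window root of the channel-mean squared error, normalized by the
global maximum of the ground truth over the test set and averaged over
windows — a dimensionless error where lower is better.  VAF is the
channel-averaged proportion of ground-truth variance explained,

    VAF = (1/C) sum_c [ 1 - Var(yhat_c - y_c) / Var(y_c) ],

reported as a percentage where 100 % is a perfect fit and a constant
predictor scores 0 (the targets are rectified and not mean-centered, so
Var(const - y) = Var(y)).
"""

from __future__ import annotations

import numpy as np

from .preprocess import TEST, WindowSet

__all__ = ["rmse", "vaf", "evaluate_method"]


def _check_shapes(yhat: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    yhat = np.atleast_2d(np.asarray(yhat, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if yhat.shape != y.shape or y.shape[0] < 1:
        raise ValueError(f"shape mismatch: yhat {yhat.shape} vs y {y.shape}")
    return yhat, y


def rmse(yhat: np.ndarray, y: np.ndarray, per_channel_max: bool = False) -> float:
    """Normalized RMSE over an (N, C) prediction/target pair.

    (1/N) sum_n sqrt((1/C) sum_c (yhat_nc - y_nc)^2) / y_max, with y_max the
    maximum of y over the whole test set (or per channel when
    ``per_channel_max`` is set, in which case the normalization happens
    inside the channel mean).
    """
    yhat, y = _check_shapes(yhat, y)
    if per_channel_max:
        ymax = y.max(axis=0)
        if (ymax <= 0).any():
            raise ValueError("per-channel maximum of the regressand must be positive")
        per_win = np.sqrt(np.mean(((yhat - y) / ymax) ** 2, axis=1))
        return float(per_win.mean())
    ymax = y.max()
    if ymax <= 0:
        raise ValueError("maximum of the regressand must be positive")
    per_win = np.sqrt(np.mean((yhat - y) ** 2, axis=1)) / ymax
    return float(per_win.mean())


def vaf(yhat: np.ndarray, y: np.ndarray) -> float:
    """Channel-averaged variance accounted for, as a fraction (1.0 = 100 %).

    Sample variances (ddof=1); the ratio is invariant to that choice.
    """
    yhat, y = _check_shapes(yhat, y)
    if y.shape[0] < 2:
        raise ValueError("VAF needs at least 2 samples")
    var_y = y.var(axis=0, ddof=1)
    bad = np.flatnonzero(var_y == 0)
    if bad.size:
        raise ValueError(f"zero-variance ground-truth channel(s) {bad.tolist()}")
    var_r = (yhat - y).var(axis=0, ddof=1)
    return float(np.mean(1.0 - var_r / var_y))


def evaluate_method(
    predict, windows: WindowSet, split: int = TEST
) -> tuple[float, float]:
    """(RMSE, VAF) of a predictor on one split of a WindowSet.

    ``predict`` maps full multichannel windows (N, W, K) to an (N, C) force
    matrix on the normalized scale (the scale models are trained on).
    """
    X, Y = windows.subset(split)
    if X.shape[0] == 0:
        raise ValueError("evaluation split is empty")
    yhat = np.asarray(predict(X))
    if yhat.shape != Y.shape:
        raise ValueError(
            f"predictor returned {yhat.shape}, expected {Y.shape}"
        )
    return rmse(yhat, Y), vaf(yhat, Y)


def assemble_channelwise(models: list) -> "callable":
    """Predictor stacking per-channel models (each with .predict and
    .target_channels) into an (N, C) matrix ordered by target channel."""

    def _predict(X: np.ndarray) -> np.ndarray:
        cols: dict[int, np.ndarray] = {}
        for m in models:
            out = m.predict(X)
            for j, c in enumerate(m.target_channels):
                cols[c] = out[:, j]
        missing = set(range(len(cols) and max(cols) + 1)) - set(cols)
        if missing:
            raise ValueError(f"no model covers force channel(s) {sorted(missing)}")
        return np.column_stack([cols[c] for c in sorted(cols)])

    return _predict
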