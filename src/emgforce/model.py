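"""Model/Results facade over the regression strategies.

`ForceRegression` is constructed from a preprocessed :class:`WindowSet` and
a method name, `fit()` trains whatever that method needs (one network per
channel, a single joint network, or the per-channel MAV+OLS baseline) and
returns a :class:`ForceRegressionResults` carrying the fitted models,
training traces, test-set metrics and a `summary()` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .architecture import ArchitectureSpec, StrategyKind, build_model, count_parameters
from .baseline import LinearModel, fit_baseline, predict_linear
from .metrics import evaluate_method
from .preprocess import TEST, SPLIT_NAMES, WindowSet
from .training import TrainConfig, TrainedModel, train_suite

__all__ = ["ForceRegression", "ForceRegressionResults", "METHODS"]

METHODS = ("linear", "one_to_one", "all_to_one", "all_to_all")


class ForceRegression:
    """A force-regression method bound to one recording's windows.

    Parameters
    ----------
    windows : WindowSet
        Normalized, split regression instances from one recording session.
    method : str
        One of ``linear``, ``one_to_one``, ``all_to_one``, ``all_to_all``.
    arch : ArchitectureSpec, optional
        Base network geometry for the LSTM methods (ignored by ``linear``).
    """

    def __init__(
        self,
        windows: WindowSet,
        method: str = "all_to_all",
        arch: ArchitectureSpec | None = None,
    ):
        if method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {method!r}")
        self.windows = windows
        self.method = method
        self.arch = arch

    def fit(self, config: TrainConfig | None = None) -> "ForceRegressionResults":
        cfg = config or TrainConfig()
        if self.method == "linear":
            models: list = fit_baseline(self.windows)
        else:
            models = train_suite(
                StrategyKind(self.method), self.windows, cfg, base=self.arch
            )
        return ForceRegressionResults(self, models, cfg)


@dataclass
class ForceRegressionResults:
    """Fitted models for one method on one recording, plus evaluation."""

    model: ForceRegression
    fitted: list
    config: TrainConfig

    @property
    def method(self) -> str:
        return self.model.method

    @property
    def n_parameters(self) -> int:
        """Total learnable parameters across all fitted models."""
        if self.method == "linear":
            return sum(m.n_parameters for m in self.fitted)
        return sum(count_parameters(m.spec) for m in self.fitted)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """(N, C) force predictions on the normalized scale."""
        if self.method == "linear":
            return predict_linear(self.fitted, X)
        C = self.model.windows.n_channels
        out = np.empty((X.shape[0], C))
        seen = set()
        for m in self.fitted:
            pred = m.predict(X)
            for j, c in enumerate(m.target_channels):
                out[:, c] = pred[:, j]
                seen.add(c)
        if seen != set(range(C)):
            raise ValueError(f"models cover channels {sorted(seen)}, need 0..{C - 1}")
        return out

    def evaluate(self, split: int = TEST) -> tuple[float, float]:
        """(RMSE, VAF fraction) on a split of the bound WindowSet."""
        return evaluate_method(self.predict, self.model.windows, split)

    def summary(self) -> str:
        ws = self.model.windows
        rmse_v, vaf_v = self.evaluate()
        lines = [
            "Force regression results",
            "========================",
            f"method:           {self.method}",
            f"models fitted:    {len(self.fitted)}",
            f"parameters total: {self.n_parameters}",
            "windows:          "
            + ", ".join(
                f"{name} {int((ws.split == i).sum())}"
                for i, name in enumerate(SPLIT_NAMES)
            ),
            f"test RMSE:        {rmse_v:.4f}",
            f"test VAF:         {100 * vaf_v:.1f} %",
        ]
        if self.method != "linear":
            epochs = [len(m.train_trace) for m in self.fitted]
            best = [m.best_epoch for m in self.fitted]
            lines.append(f"epochs trained:   {epochs} (best: {best})")
        return "\n".join(lines)
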