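"""Model fitting: AdamW on MSE with minibatches and validation early stopping.

Training stops when the validation loss has not improved for
``patience_epochs`` consecutive epochs or after ``max_epochs``, whichever
comes first, and the weights from the best-validation epoch are restored.
One model is trained per output force channel for the One-to-One and
All-to-One strategies; the All-to-All strategy trains a single model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .architecture import ArchitectureSpec, StrategyKind, build_model
from .nn import AdamW, ConvLSTMRegressor, mse_loss
from .preprocess import TRAIN, VAL, WindowSet

__all__ = ["TrainConfig", "TrainedModel", "train", "train_suite"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule settings (defaults follow the study protocol)."""

    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 1e-9
    batch_size: int = 32
    patience_epochs: int = 25
    max_epochs: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.beta1, self.beta2, self.batch_size) <= 0:
            raise ValueError("learning rate, betas and batch size must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be nonnegative")
        if not 1 <= self.patience_epochs <= self.max_epochs:
            raise ValueError("need 1 <= patience_epochs <= max_epochs")


@dataclass
class TrainedModel:
    """A fitted network plus the bookkeeping needed to use and audit it."""

    spec: ArchitectureSpec
    state: dict[str, np.ndarray]
    train_trace: list[tuple[float, float]]  # (train loss, val loss) per epoch
    seed: int
    input_channels: tuple[int, ...]
    target_channels: tuple[int, ...]
    best_epoch: int  # 1-based

    def network(self) -> ConvLSTMRegressor:
        net = ConvLSTMRegressor(self.spec, seed=self.seed)
        net.set_state(self.state)
        return net

    def predict(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Predict from full multichannel windows (N, W, K_total)."""
        return self.network().predict(X[:, :, list(self.input_channels)], batch_size)


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield idx[i : i + batch_size]  # last (possibly partial) batch included


def train(
    spec: ArchitectureSpec,
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_val: np.ndarray,
    Y_val: np.ndarray,
    cfg: TrainConfig,
    input_channels: tuple[int, ...] = (),
    target_channels: tuple[int, ...] = (),
) -> TrainedModel:
    """Fit one network; inputs are already channel-selected (N, W, in_channels)."""
    if X_train.shape[0] == 0 or X_val.shape[0] == 0:
        raise ValueError("train and validation splits must be non-empty")
    if Y_train.ndim != 2 or Y_train.shape[1] != spec.out_units:
        raise ValueError(
            f"targets must be (N, {spec.out_units}), got {Y_train.shape}"
        )
    net = ConvLSTMRegressor(spec, seed=cfg.seed)
    opt = AdamW(
        lr=cfg.learning_rate,
        beta1=cfg.beta1,
        beta2=cfg.beta2,
        weight_decay=cfg.weight_decay,
    )
    rng = np.random.default_rng(cfg.seed)
    trace: list[tuple[float, float]] = []
    best_val = np.inf
    best_state = net.get_state()
    best_epoch = 0
    stall = 0
    for epoch in range(1, cfg.max_epochs + 1):
        losses = []
        for batch in _epoch_batches(X_train.shape[0], cfg.batch_size, rng):
            try:
                loss, grads = net.loss_and_grads(X_train[batch], Y_train[batch], rng)
            except FloatingPointError as err:
                raise FloatingPointError(
                    f"epoch {epoch}: {err}; try lowering the learning rate"
                ) from err
            opt.step(net.params, grads)
            losses.append(loss)
        val_loss, _ = mse_loss(net.predict(X_val), Y_val)
        trace.append((float(np.mean(losses)), val_loss))
        if val_loss < best_val:
            best_val = val_loss
            best_state = net.get_state()
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience_epochs:
                break
    return TrainedModel(
        spec=spec,
        state=best_state,
        train_trace=trace,
        seed=cfg.seed,
        input_channels=tuple(input_channels),
        target_channels=tuple(target_channels),
        best_epoch=best_epoch,
    )


def train_suite(
    strategy: StrategyKind,
    windows: WindowSet,
    cfg: TrainConfig,
    base: ArchitectureSpec | None = None,
) -> list[TrainedModel]:
    """Train all models a strategy needs on one recording's WindowSet.

    One-to-One and All-to-One produce one model per force channel;
    All-to-All produces a single model covering all channels.
    """
    strategy = StrategyKind(strategy)
    K = windows.n_channels
    if base is None:
        base = ArchitectureSpec(window_len=windows.config.width_samples)
    spec = build_model(strategy, n_emg_channels=K, base=base)
    Xtr, Ytr = windows.subset(TRAIN)
    Xva, Yva = windows.subset(VAL)
    seeds = np.random.default_rng(cfg.seed).integers(0, 2**31 - 1, size=K + 1)

    if strategy is StrategyKind.ALL_TO_ALL:
        sub = dataclass_replace(cfg, seed=int(seeds[0]))
        return [
            train(
                spec, Xtr, Ytr, Xva, Yva, sub,
                input_channels=tuple(range(K)),
                target_channels=tuple(range(K)),
            )
        ]
    models = []
    for c in range(K):
        ins = (c,) if strategy is StrategyKind.ONE_TO_ONE else tuple(range(K))
        sub = dataclass_replace(cfg, seed=int(seeds[c + 1]))
        models.append(
            train(
                spec,
                Xtr[:, :, list(ins)],
                Ytr[:, [c]],
                Xva[:, :, list(ins)],
                Yva[:, [c]],
                sub,
                input_channels=ins,
                target_channels=(c,),
            )
        )
    return models


def dataclass_replace(cfg: TrainConfig, **kw) -> TrainConfig:
    from dataclasses import replace

    return replace(cfg, **kw)
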