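"""NumPy implementation of the Conv1D + LSTM regression network.

The network maps a raw iEMG window (W samples x K channels) to a force
vector.  Forward and backward passes are written directly against BLAS
matmuls: the convolution is an im2col product, the LSTM keeps its per-step
gate activations for backpropagation through time, and AdamW applies
decoupled weight decay (the decay term never enters the moment estimates).

Gate layout in all 4H-wide LSTM arrays is [input, forget, cell, output].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .architecture import ArchitectureSpec, count_parameters

__all__ = ["ConvLSTMRegressor", "AdamW", "mse_loss"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diagonal(r))  # fix sign ambiguity for determinism


_LN_EPS = 1e-5


def _layernorm_fwd(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv)


def _layernorm_bwd(dy, g, cache):
    xhat, inv = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


def mse_loss(yhat: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all elements, and its gradient w.r.t. yhat."""
    r = yhat - y
    return float(np.mean(r * r)), (2.0 / r.size) * r


class ConvLSTMRegressor:
    """One network instance: parameters, forward pass, manual backprop.

    Parameters are float64 arrays in a flat dict; ``n_parameters`` counts
    them by enumeration and always equals the closed-form
    :func:`~emgforce.architecture.count_parameters`.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        k, ci, f = spec.conv_kernel, spec.in_channels, spec.conv_filters
        h, f1, out = spec.lstm_units, spec.fc1_units, spec.out_units
        wh = np.concatenate([_orthogonal(rng, h) for _ in range(4)], axis=1)
        lstm_b = np.zeros(4 * h)
        lstm_b[h : 2 * h] = 1.0  # forget-gate bias
        self.params: dict[str, np.ndarray] = {
            "conv_w": _glorot(rng, k * ci, f, (k * ci, f)),
            "conv_b": np.zeros(f),
            "ln1_g": np.ones(f),
            "ln1_b": np.zeros(f),
            "lstm_wx": _glorot(rng, f, h, (f, 4 * h)),
            "lstm_wh": wh,
            "lstm_b": lstm_b,
            "ln2_g": np.ones(h),
            "ln2_b": np.zeros(h),
            "fc1_w": _glorot(rng, h, f1, (h, f1)),
            "fc1_b": np.zeros(f1),
            "fc2_w": _glorot(rng, f1, out, (f1, out)),
            "fc2_b": np.zeros(out),
        }

    @property
    def n_parameters(self) -> int:
        n = sum(p.size for p in self.params.values())
        assert n == count_parameters(self.spec)
        return n

    # -- forward ----------------------------------------------------------

    def _check_input(self, X: np.ndarray) -> None:
        if X.ndim != 3 or X.shape[2] != self.spec.in_channels:
            raise ValueError(
                f"expected input (N, W, {self.spec.in_channels}), got {X.shape}"
            )

    def _lrelu(self, x):
        s = self.spec.leaky_relu_slope
        return np.where(x > 0, x, s * x)

    def _dropout_mask(self, shape, rng):
        p = self.spec.dropout_p
        return (rng.random(shape) >= p) / (1.0 - p)

    def forward(
        self,
        X: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Predictions (N, out_units); with ``train=True`` also a backprop cache."""
        self._check_input(X)
        p = self.params
        spec = self.spec
        N, W, _ = X.shape
        k = spec.conv_kernel
        drop = train and spec.dropout_p > 0
        if drop and rng is None:
            raise ValueError("training forward pass needs an RNG for dropout")

        pl = (k - 1) // 2
        xp = np.pad(X, ((0, 0), (pl, k - 1 - pl), (0, 0)))
        patches = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        # (N, W, Cin, k) -> (N*W, k*Cin), matching conv_w's (k, Cin) flatten
        P = np.ascontiguousarray(patches.transpose(0, 1, 3, 2)).reshape(N * W, -1)
        z1 = (P @ p["conv_w"] + p["conv_b"]).reshape(N, W, -1)
        a1 = self._lrelu(z1)
        n1, ln1c = _layernorm_fwd(a1, p["ln1_g"], p["ln1_b"])
        if drop:
            m1 = self._dropout_mask(n1.shape, rng)
            d1 = n1 * m1
        else:
            m1, d1 = None, n1

        # LSTM over W steps; only the final hidden state feeds upward.
        H = spec.lstm_units
        xz = d1.reshape(N * W, -1) @ p["lstm_wx"]
        xz = xz.reshape(N, W, 4 * H)
        h = np.zeros((N, H))
        c = np.zeros((N, H))
        gates = np.empty((W, N, 4 * H)) if train else None
        cs = np.empty((W + 1, N, H)) if train else None
        hs = np.empty((W + 1, N, H)) if train else None
        tanhs = np.empty((W, N, H)) if train else None
        if train:
            cs[0] = 0.0
            hs[0] = 0.0
        wh = p["lstm_wh"]
        b = p["lstm_b"]
        for t in range(W):
            z = xz[:, t] + h @ wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            if train:
                gates[t] = np.concatenate([i, f, g, o], axis=1)
                cs[t + 1] = c
                hs[t + 1] = h
                tanhs[t] = tc
        hT = h

        a2 = self._lrelu(hT)
        n2, ln2c = _layernorm_fwd(a2, p["ln2_g"], p["ln2_b"])
        if drop:
            m2 = self._dropout_mask(n2.shape, rng)
            d2 = n2 * m2
        else:
            m2, d2 = None, n2
        z3 = d2 @ p["fc1_w"] + p["fc1_b"]
        a3 = self._lrelu(z3)
        if drop:
            m3 = self._dropout_mask(a3.shape, rng)
            d3 = a3 * m3
        else:
            m3, d3 = None, a3
        y = d3 @ p["fc2_w"] + p["fc2_b"]
        if not train:
            return y
        cache = dict(
            P=P, z1=z1, a1=a1, ln1c=ln1c, m1=m1, d1=d1, xz_in=d1,
            gates=gates, cs=cs, hs=hs, tanhs=tanhs, hT=hT,
            a2=a2, ln2c=ln2c, m2=m2, d2=d2, z3=z3, a3=a3, m3=m3, d3=d3,
            shape=(N, W),
        )
        return y, cache

    def predict(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Deterministic inference (dropout disabled), in batches."""
        self._check_input(X)
        if X.shape[0] == 0:
            return np.empty((0, self.spec.out_units))
        outs = [
            self.forward(X[i : i + batch_size])
            for i in range(0, X.shape[0], batch_size)
        ]
        return np.concatenate(outs, axis=0)

    # -- backward ---------------------------------------------------------

    def _dlrelu(self, x, dy):
        s = self.spec.leaky_relu_slope
        return np.where(x > 0, dy, s * dy)

    def backward(self, cache: dict, dy: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. every parameter, given d loss / d output."""
        p = self.params
        spec = self.spec
        N, W = cache["shape"]
        H = spec.lstm_units
        g = {}

        g["fc2_w"] = cache["d3"].T @ dy
        g["fc2_b"] = dy.sum(axis=0)
        dd3 = dy @ p["fc2_w"].T
        da3 = dd3 * cache["m3"] if cache["m3"] is not None else dd3
        dz3 = self._dlrelu(cache["z3"], da3)
        g["fc1_w"] = cache["d2"].T @ dz3
        g["fc1_b"] = dz3.sum(axis=0)
        dd2 = dz3 @ p["fc1_w"].T
        dn2 = dd2 * cache["m2"] if cache["m2"] is not None else dd2
        da2, g["ln2_g"], g["ln2_b"] = _layernorm_bwd(dn2, p["ln2_g"], cache["ln2c"])
        dhT = self._dlrelu(cache["hT"], da2)

        gates, cs, hs, tanhs = cache["gates"], cache["cs"], cache["hs"], cache["tanhs"]
        wh = p["lstm_wh"]
        dwh = np.zeros_like(wh)
        db = np.zeros_like(p["lstm_b"])
        dxz = np.empty((W, N, 4 * H))
        dh = dhT
        dc = np.zeros((N, H))
        for t in range(W - 1, -1, -1):
            i = gates[t][:, :H]
            f = gates[t][:, H : 2 * H]
            gg = gates[t][:, 2 * H : 3 * H]
            o = gates[t][:, 3 * H :]
            tc = tanhs[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * gg
            df = dc * cs[t]
            dgg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dgg * (1.0 - gg * gg),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dxz[t] = dz
            dwh += hs[t].T @ dz
            db += dz.sum(axis=0)
            dh = dz @ wh.T
            dc = dc * f
        g["lstm_wh"] = dwh
        g["lstm_b"] = db
        dxz_flat = dxz.transpose(1, 0, 2).reshape(N * W, 4 * H)
        x_in = cache["xz_in"].reshape(N * W, -1)
        g["lstm_wx"] = x_in.T @ dxz_flat
        dd1 = (dxz_flat @ p["lstm_wx"].T).reshape(N, W, -1)

        dn1 = dd1 * cache["m1"] if cache["m1"] is not None else dd1
        da1, g["ln1_g"], g["ln1_b"] = _layernorm_bwd(dn1, p["ln1_g"], cache["ln1c"])
        dz1 = self._dlrelu(cache["z1"], da1).reshape(N * W, -1)
        g["conv_w"] = cache["P"].T @ dz1
        g["conv_b"] = dz1.sum(axis=0)
        return g

    def loss_and_grads(
        self, X: np.ndarray, Y: np.ndarray, rng: np.random.Generator
    ) -> tuple[float, dict[str, np.ndarray]]:
        yhat, cache = self.forward(X, train=True, rng=rng)
        loss, dy = mse_loss(yhat, Y)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss ({loss})")
        return loss, self.backward(cache, dy)

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()


@dataclass
class AdamW:
    """Adam with decoupled weight decay.

    The decay is applied directly to the parameters (scaled by the learning
    rate), never folded into the gradient moments.
    """

    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    weight_decay: float = 1e-9
    t: int = 0
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for k, p in params.items():
            gk = grads[k]
            m = self.m.setdefault(k, np.zeros_like(p))
            v = self.v.setdefault(k, np.zeros_like(p))
            m += (1.0 - b1) * (gk - m)
            v += (1.0 - b2) * (gk * gk - v)
            p -= self.lr * ((m / bc1) / (np.sqrt(v / bc2) + self.eps)
                            + self.weight_decay * p)
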