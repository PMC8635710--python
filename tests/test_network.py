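"""Network engine: parameter accounting, forward oracle, gradients, AdamW."""

import numpy as np
import pytest

from emgforce.architecture import (
    ArchitectureSpec,
    StrategyKind,
    build_model,
    count_parameters,
)
from emgforce.nn import AdamW, ConvLSTMRegressor, mse_loss

TINY = ArchitectureSpec(
    window_len=7, in_channels=2, conv_filters=3, conv_kernel=3,
    lstm_units=4, fc1_units=3, out_units=2, dropout_p=0.0,
)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _loop_forward(net: ConvLSTMRegressor, X: np.ndarray) -> np.ndarray:
    """Independent, loop-based re-implementation of the forward pass."""
    p = {k: v for k, v in net.params.items()}
    spec = net.spec
    N, W, Cin = X.shape
    k, F, H = spec.conv_kernel, spec.conv_filters, spec.lstm_units
    s = spec.leaky_relu_slope
    pl = (k - 1) // 2
    eps = 1e-5

    def lrelu(v):
        return v if v > 0 else s * v

    def layernorm(vec, g, b):
        mu = sum(vec) / len(vec)
        var = sum((v - mu) ** 2 for v in vec) / len(vec)
        return [g[i] * (vec[i] - mu) / np.sqrt(var + eps) + b[i]
                for i in range(len(vec))]

    out = np.empty((N, spec.out_units))
    for n in range(N):
        # conv, same-padded, then lrelu + layer norm per time step
        seq = []
        for t in range(W):
            feat = []
            for f in range(F):
                acc = p["conv_b"][f]
                for dk in range(k):
                    ti = t + dk - pl
                    if 0 <= ti < W:
                        for ci in range(Cin):
                            acc += X[n, ti, ci] * p["conv_w"][dk * Cin + ci, f]
                feat.append(lrelu(acc))
            seq.append(layernorm(feat, p["ln1_g"], p["ln1_b"]))
        # LSTM, gate order [i, f, g, o]
        h = [0.0] * H
        c = [0.0] * H
        for t in range(W):
            z = [p["lstm_b"][j]
                 + sum(seq[t][a] * p["lstm_wx"][a, j] for a in range(F))
                 + sum(h[b] * p["lstm_wh"][b, j] for b in range(H))
                 for j in range(4 * H)]
            newc, newh = [], []
            for j in range(H):
                i_g = _sigmoid(z[j])
                f_g = _sigmoid(z[H + j])
                g_g = np.tanh(z[2 * H + j])
                o_g = _sigmoid(z[3 * H + j])
                cj = f_g * c[j] + i_g * g_g
                newc.append(cj)
                newh.append(o_g * np.tanh(cj))
            c, h = newc, newh
        h = layernorm([lrelu(v) for v in h], p["ln2_g"], p["ln2_b"])
        a3 = [lrelu(p["fc1_b"][j] + sum(h[a] * p["fc1_w"][a, j] for a in range(H)))
              for j in range(spec.fc1_units)]
        for j in range(spec.out_units):
            out[n, j] = p["fc2_b"][j] + sum(
                a3[a] * p["fc2_w"][a, j] for a in range(spec.fc1_units)
            )
    return out


class TestParameterCounts:
    @pytest.mark.parametrize(
        "strategy,expected",
        [
            (StrategyKind.ONE_TO_ONE, 36_801),
            (StrategyKind.ALL_TO_ONE, 43_521),
            (StrategyKind.ALL_TO_ALL, 43_686),
        ],
    )
    def test_closed_form_matches_enumeration(self, strategy, expected):
        spec = build_model(strategy, n_emg_channels=6)
        assert count_parameters(spec) == expected
        net = ConvLSTMRegressor(spec, seed=0)
        assert sum(w.size for w in net.params.values()) == expected

    def test_strategies_differ_only_in_conv_input_and_head(self):
        specs = {s: build_model(s, 6) for s in StrategyKind}
        nets = {s: ConvLSTMRegressor(spec, seed=0) for s, spec in specs.items()}
        shapes = {s: {k: v.shape for k, v in n.params.items()} for s, n in nets.items()}
        for key in shapes[StrategyKind.ONE_TO_ONE]:
            s121 = shapes[StrategyKind.ONE_TO_ONE][key]
            sa21 = shapes[StrategyKind.ALL_TO_ONE][key]
            sa2a = shapes[StrategyKind.ALL_TO_ALL][key]
            if key == "conv_w":
                assert s121 != sa21 and sa21 == sa2a
            elif key in ("fc2_w", "fc2_b"):
                assert s121 == sa21 and sa21 != sa2a
            else:
                assert s121 == sa21 == sa2a


class TestForward:
    def test_matches_loop_oracle(self, rng):
        net = ConvLSTMRegressor(TINY, seed=3)
        X = rng.standard_normal((3, TINY.window_len, TINY.in_channels))
        np.testing.assert_allclose(net.forward(X), _loop_forward(net, X), atol=1e-10)

    def test_empty_batch(self):
        net = ConvLSTMRegressor(TINY, seed=0)
        assert net.predict(np.empty((0, 7, 2))).shape == (0, 2)

    def test_inference_deterministic(self, rng):
        net = ConvLSTMRegressor(TINY, seed=0)
        X = rng.standard_normal((4, 7, 2))
        np.testing.assert_array_equal(net.forward(X), net.forward(X))

    def test_dropout_adds_variance_in_train_mode(self, rng):
        spec = ArchitectureSpec(window_len=7, in_channels=2, conv_filters=3,
                                conv_kernel=3, lstm_units=4, fc1_units=3,
                                out_units=1, dropout_p=0.2)
        net = ConvLSTMRegressor(spec, seed=0)
        X = rng.standard_normal((4, 7, 2))
        y1, _ = net.forward(X, train=True, rng=np.random.default_rng(1))
        y2, _ = net.forward(X, train=True, rng=np.random.default_rng(2))
        assert np.abs(y1 - y2).max() > 0

    def test_shape_mismatch_named(self):
        net = ConvLSTMRegressor(TINY, seed=0)
        with pytest.raises(ValueError, match=r"\(N, W, 2\)"):
            net.forward(np.zeros((1, 7, 5)))


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        net = ConvLSTMRegressor(TINY, seed=1)
        X = rng.standard_normal((5, 7, 2))
        Y = rng.standard_normal((5, 2))
        _, grads = net.loss_and_grads(X, Y, rng)
        eps = 1e-6
        for key, p in net.params.items():
            flat = p.reshape(-1)
            idx = rng.choice(flat.size, size=min(4, flat.size), replace=False)
            for i in idx:
                old = flat[i]
                flat[i] = old + eps
                lp, _ = mse_loss(net.forward(X), Y)
                flat[i] = old - eps
                lm, _ = mse_loss(net.forward(X), Y)
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[key].reshape(-1)[i]
                assert num == pytest.approx(ana, rel=1e-4, abs=1e-9), key

    def test_nan_loss_aborts(self):
        net = ConvLSTMRegressor(TINY, seed=0)
        X = np.full((2, 7, 2), np.nan)
        with pytest.raises(FloatingPointError, match="non-finite"):
            net.loss_and_grads(X, np.zeros((2, 2)), np.random.default_rng(0))


class TestAdamW:
    def test_decay_is_decoupled(self):
        # with a frozen gradient, the only difference between lambda = 0 and
        # lambda = 0.1 after one step is exactly lr * lambda * p
        p0 = np.array([2.0, -3.0])
        g = np.array([0.5, 0.5])
        p_a, p_b = p0.copy(), p0.copy()
        AdamW(lr=0.01, weight_decay=0.0).step({"p": p_a}, {"p": g})
        AdamW(lr=0.01, weight_decay=0.1).step({"p": p_b}, {"p": g})
        np.testing.assert_allclose(p_a - p_b, 0.01 * 0.1 * p0, atol=1e-12)

    def test_descends_quadratic(self):
        p = {"x": np.array([5.0])}
        opt = AdamW(lr=0.1, weight_decay=0.0)
        for _ in range(500):
            opt.step(p, {"x": 2 * p["x"]})
        assert abs(p["x"][0]) < 1e-2
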