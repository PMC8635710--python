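"""Preprocessing chain: clipping, filtering, decimation, pairing, windowing."""

import numpy as np
import pytest

from emgforce.preprocess import (
    TEST,
    TRAIN,
    VAL,
    FilterSpec,
    WindowConfig,
    PairedSignals,
    clip_percentiles,
    decimate,
    default_period_split,
    expected_window_count,
    lowpass_filter,
    normalize,
    pair_and_select,
    preprocess_recording,
    segment_windows,
    split_by_period,
    split_force_phases,
)
from emgforce.presets import demo_preprocess_kwargs


class TestClip:
    def test_ramp_clipped_to_inner_percentiles(self):
        x = np.arange(101, dtype=float)
        y = clip_percentiles(x, 1, 99)
        # linear-interpolation percentiles of 0..100 are exactly 1 and 99
        assert y.min() == 1.0 and y.max() == 99.0
        assert np.all(y[1:-1] == x[1:-1])

    def test_constant_signal_unchanged(self):
        x = np.full(50, 3.3)
        np.testing.assert_array_equal(clip_percentiles(x), x)

    def test_idempotent_with_fixed_reference(self, rng):
        x = rng.standard_normal(500)
        once = clip_percentiles(x, reference=x)
        np.testing.assert_array_equal(clip_percentiles(once, reference=x), once)

    def test_external_reference(self, rng):
        x = rng.standard_normal(100) * 100
        ref = np.linspace(-1, 1, 201)
        y = clip_percentiles(x, 1, 99, reference=ref)
        lo, hi = np.percentile(ref, [1, 99])
        assert y.min() >= lo and y.max() <= hi

    def test_bad_percentiles(self):
        with pytest.raises(ValueError):
            clip_percentiles(np.ones(5), 99, 1)


class TestLowpass:
    def test_dc_gain_unity(self):
        x = np.full(8000, 5.0)
        y = lowpass_filter(x, FilterSpec(cutoff_hz=500.0), fs=10240.0)
        assert y[-1] == pytest.approx(5.0, rel=1e-6)

    @pytest.mark.parametrize("cutoff,fs", [(500.0, 10240.0), (10.0, 10240.0)])
    def test_minus_3db_at_cutoff(self, cutoff, fs):
        t = np.arange(int(20 * fs / cutoff)) / fs
        x = np.sin(2 * np.pi * cutoff * t)
        y = lowpass_filter(x, FilterSpec(cutoff_hz=cutoff), fs=fs)
        tail = y[len(y) // 2 :]
        ratio = np.abs(tail).max()
        assert ratio == pytest.approx(1 / np.sqrt(2), rel=0.02)

    def test_attenuation_at_4x_cutoff(self):
        # analog magnitude 1/sqrt(1 + (f/fc)^(2*order)); valid for the
        # digital design while fc << Nyquist (the 10 Hz force filter)
        fs, fc = 10240.0, 10.0
        t = np.arange(int(40 * fs / fc)) / fs
        x = np.sin(2 * np.pi * 4 * fc * t)
        y = lowpass_filter(x, FilterSpec(cutoff_hz=fc), fs=fs)
        ratio = np.abs(y[len(y) // 2 :]).max()
        assert ratio == pytest.approx(1 / np.sqrt(1 + 4.0**4), rel=0.10)

    def test_causal_single_pass(self, rng):
        # changing future samples never changes past output
        x = rng.standard_normal(1000)
        spec = FilterSpec(cutoff_hz=100.0)
        y1 = lowpass_filter(x, spec, fs=1024.0)
        x2 = x.copy()
        x2[500:] += 10.0
        y2 = lowpass_filter(x2, spec, fs=1024.0)
        np.testing.assert_array_equal(y1[:500], y2[:500])

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(np.ones(10), FilterSpec(cutoff_hz=600.0), fs=1024.0)


class TestDecimate:
    def test_length_and_convention(self):
        assert decimate(np.zeros(10240), 10).shape[0] == 1024
        np.testing.assert_array_equal(
            decimate(np.arange(100), 10), np.arange(0, 100, 10)
        )

    def test_factor_one_identity(self, rng):
        x = rng.standard_normal(17)
        np.testing.assert_array_equal(decimate(x, 1), x)

    def test_bad_factor(self):
        with pytest.raises(ValueError):
            decimate(np.ones(5), 0)


class TestPhaseSplit:
    def test_stated_rule(self):
        pos, neg = split_force_phases(np.array([2.0, -3.0]), np.array([1.0, -1.0]))
        np.testing.assert_array_equal(pos, [2.0, 0.0])
        np.testing.assert_array_equal(neg, [0.0, 3.0])

    def test_all_positive_cue(self, rng):
        f = rng.standard_normal(100)
        pos, neg = split_force_phases(f, np.ones(100))
        assert np.all(neg == 0) and np.all(pos == np.abs(f))

    def test_partition_property(self, rng):
        f = rng.standard_normal(200)
        cue = rng.standard_normal(200)
        pos, neg = split_force_phases(f, cue)
        nz = cue != 0
        np.testing.assert_allclose((pos + neg)[nz], np.abs(f)[nz])
        assert np.all(pos[cue == 0] == 0) and np.all(neg[cue == 0] == 0)


def _paired(E, F, task, period, sample_index=None, fs=256.0):
    T = E.shape[0]
    return PairedSignals(
        E=E,
        F=F,
        task_code=np.asarray(task, dtype=object),
        period_index=np.asarray(period),
        sample_index=np.arange(T) if sample_index is None else np.asarray(sample_index),
        fs=fs,
    )


class TestWindows:
    def test_single_exact_window(self, rng):
        E = rng.standard_normal((512, 2))
        F = np.abs(rng.standard_normal((512, 2)))
        X, Y, per = segment_windows(
            _paired(E, F, ["1"] * 512, [1] * 512), WindowConfig(512, 64)
        )
        assert X.shape == (1, 512, 2)
        np.testing.assert_array_equal(Y[0], F[511])

    def test_window_count_1024(self, rng):
        E = rng.standard_normal((1024, 1))
        F = np.abs(E)
        X, _, _ = segment_windows(
            _paired(E, F, ["1"] * 1024, [1] * 1024), WindowConfig(512, 64)
        )
        assert X.shape[0] == 9  # floor((1024-512)/64) + 1

    def test_target_alignment_contract(self, rng):
        E = rng.standard_normal((300, 1))
        F = np.abs(rng.standard_normal((300, 1)))
        cfg = WindowConfig(64, 16)
        X, Y, _ = segment_windows(_paired(E, F, ["1"] * 300, [1] * 300), cfg)
        for n in range(X.shape[0]):
            end = cfg.width_samples - 1 + n * cfg.step_samples
            np.testing.assert_array_equal(Y[n], F[end])
            np.testing.assert_array_equal(X[n], E[end - 63 : end + 1])

    def test_windows_never_straddle_task_boundaries(self, rng):
        E = rng.standard_normal((200, 1))
        F = np.abs(E)
        task = ["1"] * 100 + ["2"] * 100
        X, _, _ = segment_windows(_paired(E, F, task, [1] * 200), WindowConfig(64, 16))
        # each segment of 100 yields floor((100-64)/16)+1 = 3 windows
        assert X.shape[0] == 6

    def test_count_matches_brute_force_enumeration(self, rng):
        # oracle: enumerate every candidate start within random segments
        cfg = WindowConfig(64, 16)
        lengths = rng.integers(1, 400, size=100).tolist()
        expected = 0
        for L in lengths:
            starts = 0
            s = 0
            while s + cfg.width_samples <= L:
                starts += 1
                s += cfg.step_samples
            expected += starts
        assert expected_window_count(lengths, cfg) == expected
        # and the windowing agrees segment by segment
        for L in lengths[:10]:
            E = rng.standard_normal((L, 1))
            X, _, _ = segment_windows(
                _paired(E, np.abs(E), ["1"] * L, [1] * L), cfg
            )
            assert X.shape[0] == expected_window_count([L], cfg)

    def test_short_segment_yields_nothing(self, rng):
        E = rng.standard_normal((10, 1))
        X, Y, _ = segment_windows(_paired(E, np.abs(E), ["1"] * 10, [1] * 10),
                                  WindowConfig(64, 16))
        assert X.shape == (0, 64, 1) and Y.shape == (0, 1)

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            WindowConfig(width_samples=32, step_samples=64)


class TestSplit:
    def test_default_ten_period_mapping(self):
        m = default_period_split(10)
        assert [m[p] for p in range(1, 11)] == [TRAIN] * 7 + [VAL] + [TEST] * 2

    def test_scaled_five_period_mapping(self):
        m = default_period_split(5)
        assert [m[p] for p in range(1, 6)] == [TRAIN] * 3 + [VAL, TEST]

    def test_window_in_period8_is_val(self):
        labels = split_by_period(np.array([8, 1, 10]), default_period_split(10))
        np.testing.assert_array_equal(labels, [VAL, TRAIN, TEST])

    def test_unknown_period_rejected(self):
        with pytest.raises(ValueError, match="not covered"):
            split_by_period(np.array([11]), default_period_split(10))

    def test_no_window_in_two_splits(self, tiny_windows):
        assert set(np.unique(tiny_windows.split)) <= {TRAIN, VAL, TEST}


class TestNormalize:
    def test_train_stats_and_round_trip(self, rng):
        X = rng.standard_normal((40, 16, 3)) * 5 + 2
        Y = np.abs(rng.standard_normal((40, 3))) * 7
        split = np.array([TRAIN] * 30 + [TEST] * 10)
        ws = normalize(X, Y, split, np.ones(40, dtype=int), 256.0, WindowConfig(16, 16))
        Xt, Yt = ws.subset(TRAIN)
        np.testing.assert_allclose(Xt.mean(axis=(0, 1)), 0, atol=1e-6)
        np.testing.assert_allclose(Xt.std(axis=(0, 1)), 1, atol=1e-6)
        np.testing.assert_allclose(Yt.std(axis=0), 1, atol=1e-6)
        assert np.all(Yt >= 0)  # no mean subtraction: sign preserved
        np.testing.assert_allclose(ws.stats.denormalize_force(ws.Y), Y, atol=1e-9)

    def test_zero_variance_channel_named(self, rng):
        X = rng.standard_normal((10, 8, 2))
        X[:, :, 1] = 0.0
        Y = np.abs(rng.standard_normal((10, 2)))
        with pytest.raises(ValueError, match=r"EMG channel\(s\) \[1\]"):
            normalize(X, Y, np.full(10, TRAIN), np.ones(10, dtype=int), 256.0,
                      WindowConfig(8, 8))

    def test_empty_train_split_rejected(self, rng):
        X = rng.standard_normal((5, 8, 1))
        Y = np.abs(rng.standard_normal((5, 1)))
        with pytest.raises(ValueError, match="training split"):
            normalize(X, Y, np.full(5, TEST), np.ones(5, dtype=int), 256.0,
                      WindowConfig(8, 8))


class TestPairing:
    def test_full_chain_shapes_and_alignment(self, tiny_recording, tiny_windows):
        ws = tiny_windows
        assert ws.X.shape[1:] == (64, 2)
        assert ws.Y.shape == (ws.X.shape[0], 2)
        assert np.all(ws.Y >= 0)

    def test_unmatched_tasks_are_discarded(self, tiny_recording):
        from dataclasses import replace

        from emgforce.simulate import Matching

        rec = tiny_recording
        rec1 = replace(
            rec, matchings=(Matching(0, 0, +1),), emg=rec.emg, force=rec.force
        )
        ws_all = preprocess_recording(rec, **demo_preprocess_kwargs())
        ws_one = preprocess_recording(rec1, **demo_preprocess_kwargs())
        assert ws_one.n_channels == 1
        # task 2's samples are gone: half the windows
        assert ws_one.n_windows == ws_all.n_windows // 2

    def test_empty_matchings_rejected(self, rng):
        with pytest.raises(ValueError, match="matchings"):
            pair_and_select(
                rng.standard_normal((100, 2)),
                np.abs(rng.standard_normal((100, 2))),
                np.ones((100, 2)),
                (),
                np.array(["1"] * 100, dtype=object),
                np.ones(100, dtype=int),
                256.0,
                {"1": 0},
            )

    def test_no_test_leakage_into_stats(self, tiny_recording):
        # normalization statistics must come from the training windows alone
        ws = preprocess_recording(tiny_recording, **demo_preprocess_kwargs())
        Xt, Yt = ws.subset(TRAIN)
        np.testing.assert_allclose(Xt.mean(axis=(0, 1)), 0, atol=1e-6)
        np.testing.assert_allclose(Xt.std(axis=(0, 1)), 1, atol=1e-6)
        np.testing.assert_allclose(Yt.std(axis=0), 1, atol=1e-6)
        Xs, Ys = ws.subset(TEST)
        assert abs(Xs.std() - 1) > 1e-8 or abs(Ys.std() - 1) > 1e-8
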