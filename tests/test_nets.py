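"""TCN / LSTM predictors: gradients, causality, equivalences, training."""

import numpy as np
import pytest

from gradpredict.core import GradientWaveform, Library, WaveformPair
from gradpredict.nets.lstm import LSTMConfig, LSTMNet
from gradpredict.nets.tcn import TCN, TCNConfig
from gradpredict.nets.train import (
    TrainingConfig,
    build_lstm,
    build_tcn,
    build_windows,
    predict_waveform,
    sliding_window_predict,
    train_model,
)

DT = 8e-6


def _finite_diff_check(net, x, tol=1e-6):
    rng = np.random.default_rng(9)
    c = rng.normal(size=x.shape[1:])
    net.forward_sequence(x)
    dx = net.backward_sequence(c)

    def loss():
        return float((net.forward_sequence(x) * c).sum())

    errs = []
    params = net.parameters()
    for p in params[:3] + params[-2:]:
        idx = tuple(0 for _ in p.data.shape)
        eps = 1e-6
        old = p.data[idx]
        p.data[idx] = old + eps
        lp = loss()
        p.data[idx] = old - eps
        lm = loss()
        p.data[idx] = old
        fd = (lp - lm) / (2 * eps)
        errs.append(abs(fd - p.grad[idx]) / max(1e-8, abs(fd)))
    i = (0, 0, x.shape[2] // 2)
    eps = 1e-6
    old = x[i]
    x[i] = old + eps
    lp = loss()
    x[i] = old - eps
    lm = loss()
    x[i] = old
    errs.append(abs((lp - lm) / (2 * eps) - dx[i]) / max(1e-8, abs(dx[i])))
    assert max(errs) < tol


class TestArchitecture:
    def test_receptive_field_closed_form(self):
        assert TCNConfig().receptive_field == 931
        assert TCNConfig(n_res_blocks=3, kernel_size=4).receptive_field == 43

    def test_receptive_field_probe_matches_closed_form(self):
        cfg = TCNConfig(
            n_res_blocks=3, kernel_size=4, channels=3, dropout=0.0,
            residual_input=False,
        )
        net = TCN(cfg, np.random.default_rng(0))
        length = cfg.receptive_field + 40
        x0 = np.zeros((2, 1, length))
        y0 = net.forward_sequence(x0)[0, -1]
        reach = 0
        for j in range(length - 1, -1, -1):
            xj = x0.copy()
            xj[0, 0, j] = 1.0
            if net.forward_sequence(xj)[0, -1] != y0:
                reach = length - j
        assert reach == cfg.receptive_field

    def test_dilations_are_powers_of_two(self):
        cfg = TCNConfig(n_res_blocks=4)
        assert cfg.dilations == [1, 2, 4, 8]

    def test_output_is_scalar_per_window(self):
        net = TCN(TCNConfig(channels=4), np.random.default_rng(0))
        win = np.random.default_rng(1).normal(size=(48, 2))
        assert np.isscalar(net.predict_window(win))

    def test_causality(self):
        """Perturbing a future sample never changes earlier outputs."""
        cfg = TCNConfig(n_res_blocks=2, kernel_size=4, channels=4, dropout=0.0)
        net = TCN(cfg, np.random.default_rng(2))
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 1, 120))
        base = net.forward_sequence(x)
        j = 60
        x2 = x.copy()
        x2[0, 0, j] += 1.0
        out = net.forward_sequence(x2)
        assert np.array_equal(out[0, :j], base[0, :j])
        assert out[0, j] != base[0, j]

    def test_tcn_gradients(self):
        cfg = TCNConfig(n_res_blocks=2, kernel_size=3, channels=4, dropout=0.0)
        net = TCN(cfg, np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(2, 3, 24))
        _finite_diff_check(net, x)

    def test_lstm_gradients(self):
        net = LSTMNet(LSTMConfig(n_layers=2, hidden=5), np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(2, 3, 12))
        _finite_diff_check(net, x, tol=1e-5)

    def test_lstm_default_config(self):
        m = build_lstm()
        assert m.config.n_layers == 2
        assert m.config.hidden == 96

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TCNConfig(n_res_blocks=0)
        with pytest.raises(ValueError):
            TCNConfig(dropout=1.0)
        with pytest.raises(ValueError):
            LSTMConfig(n_layers=0)


class TestWindows:
    def _tiny_pairs(self, n_waves=3, n=30):
        rng = np.random.default_rng(5)
        pairs = []
        for _ in range(n_waves):
            x = rng.normal(size=n) * 50
            nom = GradientWaveform(x, DT, axis="z")
            meas = GradientWaveform(x * 0.9, DT, axis="z", amp_scale=nom.amp_scale)
            pairs.append(WaveformPair(nom, meas))
        return pairs

    def test_one_sample_per_time_point(self):
        pairs = self._tiny_pairs()
        wins, targets = build_windows(pairs, window_length=8)
        assert wins.shape == (3 * 30, 8, 2)
        assert targets.shape == (3 * 30,)

    def test_amplitude_channel_constant(self):
        pairs = self._tiny_pairs()
        wins, _ = build_windows(pairs, window_length=8, a_sys=770.0)
        assert np.allclose(np.ptp(wins[:, :, 1], axis=1), 0.0)

    def test_normalized_channel_bounded(self):
        pairs = self._tiny_pairs()
        wins, _ = build_windows(pairs, window_length=8)
        assert np.max(np.abs(wins[:, :, 0])) <= 1.0 + 1e-9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_windows([], window_length=8)


class TestTraining:
    def _identity_library(self, n_waves=6, n=160):
        rng = np.random.default_rng(6)
        pairs = []
        for i in range(n_waves):
            t = np.arange(n) * DT
            x = (
                rng.uniform(50, 300)
                * np.sin(2 * np.pi * rng.uniform(500, 4000) * t)
                * np.hanning(n)
            )
            nom = GradientWaveform(x, DT, axis="z")
            meas = GradientWaveform(x.copy(), DT, axis="z", amp_scale=nom.amp_scale)
            pairs.append(WaveformPair(nom, meas))
        return Library(pairs)

    def test_identity_system_reaches_low_mae(self):
        lib = self._identity_library()
        m = build_tcn(TCNConfig(channels=6, dropout=0.0), axis="z", seed=0)
        tcfg = TrainingConfig(epochs=5, rng_seed=0)
        train_model(m, lib.pairs, tcfg)
        assert m.loss_trace[-1] < 1e-3

    def test_loss_trace_length(self):
        lib = self._identity_library(n_waves=3, n=60)
        m = build_tcn(TCNConfig(channels=4, n_res_blocks=2), axis="z", seed=0)
        train_model(m, lib.pairs, TrainingConfig(epochs=4, rng_seed=0))
        assert len(m.loss_trace) == 4

    def test_training_deterministic(self):
        lib = self._identity_library(n_waves=3, n=60)
        finals = []
        for _ in range(2):
            m = build_tcn(
                TCNConfig(channels=4, n_res_blocks=2, dropout=0.1), axis="z", seed=3
            )
            train_model(m, lib.pairs, TrainingConfig(epochs=3, rng_seed=3))
            finals.append(m.loss_trace[-1])
        assert finals[0] == pytest.approx(finals[1], rel=1e-6)

    def test_lstm_accepts_same_dataset_and_trains(self):
        lib = self._identity_library(n_waves=3, n=60)
        m = build_lstm(n_layers=1, hidden=8, axis="z", seed=0)
        train_model(m, lib.pairs, TrainingConfig(epochs=3, rng_seed=0))
        assert len(m.loss_trace) == 3
        assert m.loss_trace[-1] <= m.loss_trace[0]

    def test_lstm_deterministic_inference(self):
        m = build_lstm(n_layers=1, hidden=8, axis="z", seed=0)
        w = GradientWaveform(np.sin(np.arange(50) / 5) * 100, DT, axis="z")
        a = predict_waveform(m, w)
        b = predict_waveform(m, w)
        assert np.array_equal(a.samples, b.samples)


class TestPrediction:
    def test_two_path_equivalence(self):
        m = build_tcn(
            TCNConfig(n_res_blocks=3, kernel_size=4, channels=6), axis="z", seed=1
        )
        rng = np.random.default_rng(3)
        w = GradientWaveform(rng.normal(size=200) * 50, DT, axis="z", amp_scale=350.0)
        full = predict_waveform(m, w)
        sw = sliding_window_predict(m, w)
        rel = np.max(np.abs(full.samples - sw.samples)) / np.max(np.abs(full.samples))
        assert rel < 1e-6

    def test_axis_mismatch_rejected(self):
        m = build_tcn(TCNConfig(channels=4, n_res_blocks=2), axis="z", seed=0)
        w = GradientWaveform(np.ones(10), DT, axis="x")
        with pytest.raises(ValueError):
            predict_waveform(m, w)

    def test_zero_input_maps_to_zero(self):
        m = build_tcn(TCNConfig(channels=4, n_res_blocks=2), axis="z", seed=0)
        w = GradientWaveform(np.zeros(20), DT, axis="z", amp_scale=0.0)
        out = predict_waveform(m, w)
        assert np.allclose(out.samples, 0.0)
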