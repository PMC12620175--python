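"""Waveform designers: analytic areas, slew feasibility, library structure."""

import numpy as np
import pytest

from gradpredict.trajectory import integrate_shotset
from gradpredict.waveforms import (
    SYSTEM_SLEW,
    LibraryConfig,
    build_characterization_library,
    make_chirp,
    make_multisine,
    make_rosette,
    make_spiral_inout,
    make_trapezoid,
    make_triangle_train,
    scale_to_amplitudes,
)

DT = 4e-6


class TestTrapezoid:
    def test_analytic_area(self):
        w = make_trapezoid(100.0, 1e-3, 0.1e-3, DT)
        area = np.trapezoid(w.samples, dx=DT) * 1e-3  # T*s/m
        assert area == pytest.approx(1.1e-4, rel=1e-9)

    def test_zero_plateau_degenerates_to_triangle(self):
        w = make_trapezoid(80.0, 0.0, 0.2e-3, DT)
        assert np.max(np.abs(w.samples)) == pytest.approx(80.0)
        assert np.count_nonzero(w.samples == 80.0) == 1

    def test_zero_amplitude_gives_zero_waveform(self):
        w = make_trapezoid(0.0, 1e-3, 0.1e-3, DT)
        assert np.all(w.samples == 0.0)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            make_trapezoid(100.0, -1e-3, 0.1e-3, DT)
        with pytest.raises(ValueError):
            make_trapezoid(100.0, 1e-3, DT / 2, DT)


class TestTriangleTrain:
    def test_even_train_is_zero_mean(self):
        w = make_triangle_train(120.0, 2, 0.2e-3, DT)
        assert abs(np.sum(w.samples)) < 1e-9

    def test_single_triangle_peak(self):
        w = make_triangle_train(120.0, 1, 0.2e-3, DT)
        assert np.max(np.abs(w.samples)) == pytest.approx(120.0)

    def test_numeric_slew_matches_ramp(self):
        peak, ramp = 90.0, 0.18e-3
        w = make_triangle_train(peak, 3, ramp, DT)
        assert np.max(np.abs(np.diff(w.samples))) / DT == pytest.approx(
            peak / ramp, rel=1e-9
        )

    def test_short_ramp_rejected(self):
        with pytest.raises(ValueError):
            make_triangle_train(100.0, 2, DT / 2, DT)


class TestChirp:
    def test_starts_at_zero(self):
        w = make_chirp(0.0, 15e3, 10e-3, 300.0, 5270.0, DT)
        assert w.samples[0] == 0.0

    def test_numeric_slew_bounded(self):
        w = make_chirp(0.0, 15e3, 10e-3, 300.0, 5270.0, DT)
        assert np.max(np.abs(np.diff(w.samples))) * 1e-3 / DT <= 5270.0

    def test_zero_peak_gives_zeros(self):
        w = make_chirp(0.0, 10e3, 2e-3, 0.0, 5270.0, DT)
        assert np.all(w.samples == 0.0)

    def test_super_nyquist_rejected(self):
        with pytest.raises(ValueError):
            make_chirp(0.0, 1.0 / DT, 2e-3, 100.0, 5270.0, DT)


class TestMultisine:
    def test_single_tone_spectrum_peak(self):
        f = 2000.0
        w = make_multisine([f], [80.0], 4e-3, DT)
        spec = np.abs(np.fft.rfft(w.samples))
        freqs = np.fft.rfftfreq(w.n, DT)
        assert freqs[np.argmax(spec)] == pytest.approx(f, abs=freqs[1])

    def test_opposite_tones_cancel(self):
        w = make_multisine([1500.0, 1500.0], [60.0, -60.0], 2e-3, DT)
        assert np.all(w.samples == 0.0)

    def test_zero_amps_give_zeros(self):
        w = make_multisine([1000.0, 2000.0], [0.0, 0.0], 2e-3, DT)
        assert np.all(w.samples == 0.0)

    def test_empty_freqs_rejected(self):
        with pytest.raises(ValueError):
            make_multisine([], [], 2e-3, DT)


class TestSpiralInOut:
    @pytest.fixture(scope="class")
    def spiral(self):
        return make_spiral_inout(8, 0.03, 0.6e-3, max_grad=140.0, dt=DT)

    def test_echo_passes_through_center(self, spiral):
        traj = integrate_shotset(spiral)[0]
        r_echo = np.linalg.norm(traj.coordinates[spiral.echo_index])
        assert r_echo < 0.01 * spiral.k_max

    def test_radius_within_k_max(self, spiral):
        for traj in integrate_shotset(spiral):
            assert traj.radius().max() <= spiral.k_max * 1.02

    def test_uniform_rotation_between_shots(self):
        ss = make_spiral_inout(
            8, 0.03, 0.6e-3, max_grad=140.0, dt=DT, prephaser=False
        )
        t0 = integrate_shotset(ss)[0].coordinates
        m = 3
        ang = 2 * np.pi * m / ss.n_shots
        rot = np.array(
            [[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]]
        )
        tm = integrate_shotset(ss)[m].coordinates
        assert np.allclose(tm, t0 @ rot.T, atol=1e-6 * ss.k_max)

    def test_prephaser_reaches_spiral_start(self, spiral):
        # with the prephaser, k at adc_start equals the spiral edge radius
        traj = integrate_shotset(spiral)[0]
        r_start = np.linalg.norm(traj.coordinates[spiral.adc_start])
        assert r_start == pytest.approx(spiral.k_max, rel=0.02)

    def test_infeasible_design_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            make_spiral_inout(2, 0.03, 0.3e-3, max_grad=0.0, dt=DT)
        with pytest.raises(ValueError, match="infeasible"):
            make_spiral_inout(2, 0.03, 0.3e-3, slew_limit=-5.0, dt=DT)


class TestRosette:
    @pytest.fixture(scope="class")
    def rosette(self):
        return make_rosette(4, 5, 0.03, 0.6e-3, 5.0e-3, dt=DT)

    def test_starts_and_ends_at_center(self, rosette):
        traj = integrate_shotset(rosette)[0]
        assert np.linalg.norm(traj.coordinates[0]) < 1e-6 * rosette.k_max
        assert np.linalg.norm(traj.coordinates[-1]) < 5e-3 * rosette.k_max

    def test_radius_within_k_max(self, rosette):
        for traj in integrate_shotset(rosette):
            assert traj.radius().max() <= rosette.k_max * 1.005

    def test_petal_count_from_zero_crossings(self, rosette):
        # n_petals lobes of |sin| => n_petals - 1 interior center passes
        traj = integrate_shotset(rosette)[0]
        r = traj.radius() / rosette.k_max
        idx = np.where(r < 0.01)[0]
        groups = np.split(idx, np.where(np.diff(idx) > 1)[0] + 1)
        interior = [g for g in groups if g[0] > 3 and g[-1] < r.size - 4]
        assert len(interior) == 5 - 1

    def test_integration_recovers_analytic_k(self, rosette):
        # gradients are analytic; trapezoidal integration must recover k(t)
        n = rosette.n_samples
        traj = integrate_shotset(rosette)[0]
        from gradpredict.waveforms import _speed_profile

        lam = _speed_profile(n)
        a1 = np.pi * 5 * lam
        a2 = np.pi * 4 * lam
        kx = rosette.k_max * np.sin(a1) * np.cos(a2)
        ky = rosette.k_max * np.sin(a1) * np.sin(a2)
        err = np.hypot(traj.coordinates[:, 0] - kx, traj.coordinates[:, 1] - ky)
        assert err.max() < 0.005 * rosette.k_max

    def test_non_integer_duration_rejected(self):
        with pytest.raises(ValueError):
            make_rosette(4, 5, 0.03, 0.6e-3, 5.0e-3 + DT / 3, dt=DT)


class TestScaleToAmplitudes:
    def test_identity_scale(self):
        w = make_trapezoid(100.0, 1e-3, 0.2e-3, DT)
        (out,) = scale_to_amplitudes(w, [100.0])
        assert np.array_equal(out.samples, w.samples)

    def test_sign_flip(self):
        w = make_trapezoid(100.0, 1e-3, 0.2e-3, DT)
        (out,) = scale_to_amplitudes(w, [-100.0])
        assert np.array_equal(out.samples, -w.samples)

    def test_amplitude_grid_spacing(self):
        amps = np.linspace(70.0, 700.0, 15)
        assert np.allclose(np.diff(amps), 45.0)
        w = make_trapezoid(100.0, 1e-3, 0.2e-3, DT)
        outs = scale_to_amplitudes(w, list(amps))
        peaks = [np.max(np.abs(o.samples)) for o in outs]
        assert np.allclose(peaks, amps)

    def test_above_system_max_warns(self):
        w = make_trapezoid(100.0, 1e-3, 0.2e-3, DT)
        with pytest.warns(UserWarning):
            scale_to_amplitudes(w, [800.0])

    def test_zero_amplitude_rejected(self):
        w = make_trapezoid(100.0, 1e-3, 0.2e-3, DT)
        with pytest.raises(ValueError):
            scale_to_amplitudes(w, [0.0])


class TestLibrary:
    def test_default_split_counts(self, lib_z):
        train_labels = set(lib_z.labels("train"))
        val_labels = set(lib_z.labels("validation"))
        assert len(train_labels) == 11
        assert len(val_labels) == 7
        assert train_labels.isdisjoint(val_labels)

    def test_amplitude_replication(self, lib_z):
        train = lib_z.subset("train")
        val = lib_z.subset("validation")
        assert len(train) == 11 * 15
        assert len(val) == 7 * 7

    def test_waveforms_start_and_end_at_zero(self, lib_z):
        for p in lib_z:
            w = p.nominal
            assert abs(w.samples[0]) <= 0.01 * abs(w.amp_scale)
            assert abs(w.samples[-1]) <= 0.01 * abs(w.amp_scale)

    def test_slew_budget_outside_demanding_shapes(self, lib_z):
        # chirps (and the most slew-demanding multisine copies) may engage
        # the amplifier's rate limiter by design; everything else respects
        # the system slew limit at every library amplitude
        demanding = {"chirp_fast", "chirp_val", "multisine_high"}
        for p in lib_z:
            if p.nominal.label in demanding:
                continue
            s = p.nominal.numeric_slew().max()
            assert s <= SYSTEM_SLEW * (1 + 1e-9), p.nominal.label

    def test_deterministic(self):
        cfg = LibraryConfig(axes=("x",), dt=8e-6)
        a = build_characterization_library(cfg)
        b = build_characterization_library(cfg)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.nominal.samples, pb.nominal.samples)
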