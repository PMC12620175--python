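"""Acquisition simulation, density compensation and gridding reconstruction."""

import numpy as np
import pytest

from gradpredict.recon import (
    B0Map,
    KaiserBesselGridder,
    KSpaceData,
    ReconImage,
    compute_dcf,
    image_error,
    make_b0_map,
    make_phantom,
    reconstruct,
    simulate_acquisition,
)
from gradpredict.trajectory import KTrajectory, integrate_shotset
from gradpredict.waveforms import make_rosette

N = 64
FOV = 0.03


@pytest.fixture(scope="module")
def readout():
    """Fully sampled rosette readout for recon tests (24 x 5 petal passes)."""
    return make_rosette(24, 5, FOV, 2 * FOV / N, 3.0e-3, dt=8e-6)


@pytest.fixture(scope="module")
def trajs(readout):
    return integrate_shotset(readout)


@pytest.fixture(scope="module")
def dcf(trajs):
    return compute_dcf(trajs, N, FOV, n_iter=25)


class TestPhantom:
    def test_point_phantom_sum(self):
        ph = make_phantom("point", n=N, fov=FOV)
        assert ph.image.sum() == 1.0

    def test_brick_has_low_signal_inclusion(self):
        ph = make_phantom("brick", n=N, fov=FOV)
        assert ph.labels["brick"].sum() > 0
        assert np.all(ph.image[ph.labels["brick"]] == 0.15)
        assert np.all(ph.image[ph.labels["background"]] == 1.0)

    def test_deterministic(self):
        a = make_phantom("brain_like", n=N, fov=FOV)
        b = make_phantom("brain_like", n=N, fov=FOV)
        assert np.array_equal(a.image, b.image)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_phantom("cube", n=N, fov=FOV)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            make_phantom("point", n=16, fov=FOV)


class TestAcquisition:
    def test_centered_point_gives_flat_magnitude(self, trajs):
        ph = make_phantom("point", n=N, fov=FOV)
        data = simulate_acquisition(ph, trajs)
        assert np.allclose(np.abs(data.samples), 1.0)

    def test_zero_phantom_gives_zero_data(self, trajs):
        ph = make_phantom("point", n=N, fov=FOV)
        ph.image[:] = 0.0
        data = simulate_acquisition(ph, trajs)
        assert np.allclose(data.samples, 0.0)

    def test_fourier_shift_theorem(self, trajs):
        ph = make_phantom("point", n=N, fov=FOV)
        shift_px = 5
        ph2 = make_phantom("point", n=N, fov=FOV)
        ph2.image[:] = np.roll(ph.image, shift_px, axis=0)
        d1 = simulate_acquisition(ph, trajs)
        d2 = simulate_acquisition(ph2, trajs)
        dx = shift_px * FOV / N
        kx = np.concatenate([t.coordinates[:, 0] for t in trajs])
        expect = d1.samples * np.exp(-2j * np.pi * kx * dx)
        assert np.allclose(d2.samples, expect)

    def test_beyond_nyquist_rejected(self):
        ph = make_phantom("point", n=N, fov=FOV)
        k = np.full((100, 2), 1.2 * N / (2 * FOV))
        traj = KTrajectory(k, times=np.arange(100) * 8e-6)
        with pytest.raises(ValueError):
            simulate_acquisition(ph, [traj])

    def test_noise_reproducible(self, trajs):
        ph = make_phantom("brick", n=N, fov=FOV)
        a = simulate_acquisition(ph, trajs, noise_sigma=0.1, seed=3)
        b = simulate_acquisition(ph, trajs, noise_sigma=0.1, seed=3)
        assert np.array_equal(a.samples, b.samples)


class TestDCF:
    def test_uniform_grid_interior_weights_constant(self):
        # a uniform Cartesian sample cloud has a flat-density fixed point
        half = N // 2
        g = (np.arange(N) - half) / FOV / N * N / 2 / half  # cycles/m grid
        g = (np.arange(N) - half) * (1.0 / FOV)
        kx, ky = np.meshgrid(g, g, indexing="ij")
        traj = KTrajectory(
            np.column_stack([kx.ravel(), ky.ravel()]),
            times=np.zeros(N * N),
        )
        w = compute_dcf([traj], N, FOV, n_iter=10)
        interior = (
            (np.abs(kx.ravel()) < 0.35 * N / FOV / 2)
            & (np.abs(ky.ravel()) < 0.35 * N / FOV / 2)
        )
        wi = w[interior]
        assert np.ptp(wi) / np.mean(wi) < 0.01

    def test_scale_invariant_fixed_point(self, trajs, dcf):
        coords = np.concatenate([t.coordinates[:, :2] for t in trajs])
        gridder = KaiserBesselGridder(coords, N, FOV)
        w0 = 2.0 * np.ones(coords.shape[0])
        w = w0
        for _ in range(10):
            w = w / np.real(gridder.interpolate(gridder.spread(w)))
        assert np.allclose(w, dcf, rtol=1e-2)

    def test_weights_positive(self, dcf):
        assert np.all(dcf > 0)

    def test_analytic_radial(self, trajs):
        w = compute_dcf(trajs, N, FOV, method="analytic_radial")
        assert np.all(w > 0)
        r = np.concatenate([t.radius() for t in trajs])
        order = np.argsort(r)
        assert w[order][-1] == w.max()


class TestReconstruct:
    def test_b0_segments_inert_without_offresonance(self, readout, trajs, dcf):
        ph = make_phantom("brick", n=N, fov=FOV)
        data = simulate_acquisition(ph, trajs, echo_index=readout.echo_index)
        zero_b0 = B0Map(delta_f=np.zeros((N, N)))
        img1 = reconstruct(data, dcf, N, FOV, b0=zero_b0, n_segments=1)
        img8 = reconstruct(data, dcf, N, FOV, b0=zero_b0, n_segments=8)
        peak = np.max(np.abs(img1.image))
        assert np.max(np.abs(img1.image - img8.image)) < 1e-8 * peak

    def test_point_spread_function(self, trajs, dcf):
        ph = make_phantom("point", n=N, fov=FOV)
        data = simulate_acquisition(ph, trajs)
        img = np.abs(reconstruct(data, dcf, N, FOV).image)
        peak_idx = np.unravel_index(np.argmax(img), img.shape)
        assert peak_idx == (N // 2, N // 2)
        # sidelobes measured outside the 7x7 mainlobe region (the first
        # diffraction ring of the disc aperture is part of the mainlobe)
        sidelobe = img.copy()
        sidelobe[
            N // 2 - 3 : N // 2 + 4, N // 2 - 3 : N // 2 + 4
        ] = 0.0
        assert img.max() / sidelobe.max() > 10

    def test_true_trajectory_beats_distorted(self, readout):
        """Reconstructing with the wrong (nominal) trajectory while data came
        from the distorted system increases error vs the phantom."""
        from gradpredict.simulator import GradientSystemModel, simulate_measurement
        from gradpredict.trajectory import integrate_gradients

        model = GradientSystemModel(rng_seed=0)
        nom_trajs, meas_trajs = [], []
        for gx, gy in readout.shots:
            nom_trajs.append(
                integrate_gradients((gx, gy), k_max=readout.k_max)
            )
            mx = simulate_measurement(model, gx, add_noise=False)
            my = simulate_measurement(model, gy, add_noise=False)
            meas_trajs.append(
                integrate_gradients((mx, my), k_max=readout.k_max)
            )
        ph = make_phantom("brick", n=N, fov=FOV)
        data = simulate_acquisition(ph, meas_trajs, echo_index=readout.echo_index)
        img_true = reconstruct(
            data, compute_dcf(meas_trajs, N, FOV), N, FOV, provenance="measured"
        )
        data_nom = KSpaceData(
            samples=data.samples,
            trajectories=nom_trajs,
            times=data.times,
            shot_lengths=data.shot_lengths,
        )
        img_nom = reconstruct(
            data_nom, compute_dcf(nom_trajs, N, FOV), N, FOV, provenance="nominal"
        )
        ref = ReconImage(image=ph.image.astype(complex), fov=FOV)

        def scaled_err(img):
            a = np.abs(img.image).ravel()
            b = ph.image.ravel()
            alpha = a @ b / (a @ a)
            return image_error(
                ReconImage(image=alpha * img.image, fov=FOV), ref
            )["nrmse"]

        assert scaled_err(img_true) < scaled_err(img_nom)

    def test_invalid_segments_rejected(self, trajs, dcf):
        ph = make_phantom("point", n=N, fov=FOV)
        data = simulate_acquisition(ph, trajs)
        with pytest.raises(ValueError):
            reconstruct(data, dcf, N, FOV, b0=make_b0_map(N), n_segments=0)


class TestImageError:
    def _img(self, arr):
        return ReconImage(image=np.asarray(arr, complex), fov=FOV)

    def test_identical_images(self, rng):
        img = self._img(rng.normal(size=(N, N)))
        assert image_error(img, img)["nrmse"] == 0.0

    def test_constant_offset_closed_form(self, rng):
        base = np.abs(rng.normal(size=(N, N))) + 1.0
        c = 0.25
        out = image_error(self._img(base + c), self._img(base))
        assert out["nrmse"] == pytest.approx(c / base.max())

    def test_joint_phase_rotation_invariant(self, rng):
        a = rng.normal(size=(N, N)) + 1j * rng.normal(size=(N, N))
        b = rng.normal(size=(N, N)) + 1j * rng.normal(size=(N, N))
        e0 = image_error(self._img(a), self._img(b))["nrmse"]
        ph = np.exp(1j * 1.1)
        e1 = image_error(self._img(a * ph), self._img(b * ph))["nrmse"]
        assert e1 == pytest.approx(e0, rel=1e-12)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            image_error(self._img(np.ones((8, 8))), self._img(np.zeros((8, 8))))
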