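"""k-space trajectories from gradient waveforms, and error metrics.

k(t) = gamma_bar * integral_0^t G(tau) dtau, in cycles/m, evaluated by
cumulative trapezoidal integration (second-order accurate in the raster
time).  Waveform NRMSE is normalized by the nominal peak amplitude;
trajectory RMSE is the RMS Euclidean per-sample error, optionally in
normalized k-space units (divided by the reference k_max).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .core import GAMMA_BAR, GradientWaveform, ShotSet


@dataclass
class KTrajectory:
    """Per-sample k-space coordinates for one shot, in cycles/m."""

    coordinates: np.ndarray  # (n, 2) or (n, 3)
    times: np.ndarray  # s
    k_max: float | None = None  # normalization constant, cycles/m
    normalized: bool = False

    def __post_init__(self) -> None:
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("trajectory coordinates must be finite")
        if self.coordinates.shape[0] != self.times.size:
            raise ValueError("coordinates/times length mismatch")

    @property
    def n(self) -> int:
        return self.coordinates.shape[0]

    def radius(self) -> np.ndarray:
        return np.linalg.norm(self.coordinates, axis=1)

    def slice_from(self, start: int) -> "KTrajectory":
        """Tail of the trajectory (e.g. the ADC-on readout after a prephaser)."""
        return KTrajectory(
            self.coordinates[start:],
            self.times[start:] - self.times[start],
            k_max=self.k_max,
            normalized=self.normalized,
        )

    def normalize(self) -> "KTrajectory":
        if self.k_max is None or self.k_max <= 0:
            raise ValueError("k_max must be set to normalize")
        return KTrajectory(
            self.coordinates / self.k_max, self.times, k_max=1.0, normalized=True
        )


def integrate_gradients(
    waveforms: tuple[GradientWaveform, ...] | list[GradientWaveform],
    gamma_bar: float = GAMMA_BAR,
    k_max: float | None = None,
) -> KTrajectory:
    """Integrate per-axis gradient waveforms into a k-space trajectory.

    Waveforms (one per spatial axis, in order) must share dt and length.
    """
    ws = list(waveforms)
    if not ws:
        raise ValueError("need at least one axis waveform")
    n = ws[0].n
    dt = ws[0].dt
    for w in ws:
        if w.n != n or w.dt != dt:
            raise ValueError("axis waveforms must share dt and length")
    coords = np.stack(
        [
            cumulative_trapezoid(w.samples * 1e-3, dx=dt, initial=0.0) * gamma_bar
            for w in ws
        ],
        axis=1,
    )
    return KTrajectory(coords, times=np.arange(n) * dt, k_max=k_max)


def integrate_shotset(
    shots: ShotSet, gamma_bar: float = GAMMA_BAR
) -> list[KTrajectory]:
    """Integrate every shot of a 2-D readout."""
    return [
        integrate_gradients((gx, gy), gamma_bar=gamma_bar, k_max=shots.k_max)
        for gx, gy in shots.shots
    ]


def waveform_nrmse(pred: GradientWaveform, meas: GradientWaveform) -> float:
    """RMS error normalized by the nominal peak amplitude |amp_scale|."""
    if pred.n != meas.n:
        raise ValueError("waveform length mismatch")
    denom = abs(pred.amp_scale)
    if denom == 0:
        denom = abs(meas.amp_scale)
    if denom == 0:
        raise ValueError("zero amp_scale: NRMSE undefined")
    return float(np.sqrt(np.mean((pred.samples - meas.samples) ** 2)) / denom)


def trajectory_rmse(
    pred: KTrajectory, ref: KTrajectory, normalize: bool = True
) -> float:
    """RMS Euclidean per-sample error; in k_max units when ``normalize``."""
    if pred.n != ref.n:
        raise ValueError("trajectory length mismatch")
    err = np.linalg.norm(pred.coordinates - ref.coordinates, axis=1)
    rmse = float(np.sqrt(np.mean(err**2)))
    if normalize:
        k_max = ref.k_max if ref.k_max else pred.k_max
        if not k_max:
            raise ValueError("k_max required for normalized trajectory RMSE")
        rmse /= k_max
    return rmse


def mean_shot_rmse(
    pred: list[KTrajectory], ref: list[KTrajectory], normalize: bool = True
) -> float:
    """Mean normalized RMSE across the shots of a readout."""
    if len(pred) != len(ref):
        raise ValueError("shot count mismatch")
    return float(
        np.mean([trajectory_rmse(p, r, normalize) for p, r in zip(pred, ref)])
    )
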