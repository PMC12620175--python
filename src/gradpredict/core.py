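"""Core containers for gradient waveforms, waveform libraries, and shot sets.

Amplitudes are in mT/m throughout, times in seconds.  A waveform's
``amp_scale`` is the signed peak *nominal* amplitude the system was asked to
play; simulated/measured waveforms keep the nominal ``amp_scale`` so that
normalization conventions (NRMSE denominators, network input scaling) always
refer to the commanded amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

AXES = ("x", "y", "z")

#: Gyromagnetic ratio of 1H over 2*pi, Hz/T.
GAMMA_BAR = 42.577478518e6

#: Default gradient raster time, seconds.
DEFAULT_DT = 4e-6


@dataclass
class GradientWaveform:
    """Uniformly sampled single-axis gradient waveform.

    Parameters
    ----------
    samples:
        Gradient amplitude series in mT/m.
    dt:
        Raster time in seconds (> 0).
    axis:
        Physical gradient axis, one of ``{"x", "y", "z"}``.
    amp_scale:
        Signed peak nominal amplitude A in mT/m.  For nominal waveforms
        ``max(|samples|) == |amp_scale|``.
    label:
        Waveform class name (e.g. ``"chirp_fast"``).
    """

    samples: np.ndarray
    dt: float
    axis: str = "z"
    amp_scale: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("waveform must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform samples must be finite")
        if self.dt <= 0:
            raise ValueError("raster time dt must be positive")
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")
        if self.amp_scale is None:
            self.amp_scale = signed_peak(self.samples)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Total duration (n * dt), seconds."""
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) * self.dt

    def numeric_slew(self) -> np.ndarray:
        """Finite-difference slew rate |dG/dt| in T/m/s (length n-1)."""
        return np.abs(np.diff(self.samples)) * 1e-3 / self.dt

    def validate_nominal(self, rtol: float = 1e-9) -> None:
        """Check the nominal-waveform invariant max|samples| == |amp_scale|."""
        peak = np.max(np.abs(self.samples))
        ref = abs(self.amp_scale)
        if ref == 0.0:
            if peak != 0.0:
                raise ValueError("zero amp_scale but nonzero samples")
            return
        if abs(peak - ref) > rtol * ref:
            raise ValueError(
                f"peak amplitude {peak} inconsistent with amp_scale {self.amp_scale}"
            )

    def with_samples(self, samples: np.ndarray, **kw) -> "GradientWaveform":
        """Copy carrying over metadata, replacing the sample array."""
        out = replace(self, samples=np.asarray(samples, dtype=float))
        for k, v in kw.items():
            setattr(out, k, v)
        return out


def signed_peak(x: np.ndarray) -> float:
    """Value of the largest-magnitude sample (sign preserved)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return 0.0
    return float(x[np.argmax(np.abs(x))])


@dataclass
class WaveformPair:
    """A nominal waveform and (optionally) its measured/simulated partner."""

    nominal: GradientWaveform
    measured: GradientWaveform | None = None
    split: str = "train"  # 'train' | 'validation' | 'test'

    def __post_init__(self) -> None:
        if self.split not in ("train", "validation", "test"):
            raise ValueError(f"unknown split {self.split!r}")
        if self.measured is not None:
            if self.measured.n != self.nominal.n:
                raise ValueError("measured/nominal length mismatch")
            if self.measured.dt != self.nominal.dt:
                raise ValueError("measured/nominal dt mismatch")


@dataclass
class Library:
    """Collection of waveform pairs with train/validation split labels."""

    pairs: list[WaveformPair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[WaveformPair]:
        return iter(self.pairs)

    def subset(self, split: str | None = None, axis: str | None = None) -> "Library":
        out = [
            p
            for p in self.pairs
            if (split is None or p.split == split)
            and (axis is None or p.nominal.axis == axis)
        ]
        return Library(out)

    def axes(self) -> list[str]:
        return sorted({p.nominal.axis for p in self.pairs})

    def labels(self, split: str | None = None) -> list[str]:
        return sorted({p.nominal.label for p in self.subset(split)})


@dataclass
class ShotSet:
    """Multi-shot 2-D readout: per shot one x- and one y-axis waveform.

    ``echo_index`` marks the sample where the trajectory is designed to pass
    through the k-space center (the echo for spin-echo acquisitions).
    """

    shots: list[tuple[GradientWaveform, GradientWaveform]]
    readout_duration: float
    echo_index: int = 0
    adc_start: int = 0  # first sample of the readout (after any prephaser)
    k_max: float | None = None  # cycles/m
    fov: float | None = None  # m
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.shots) < 1:
            raise ValueError("ShotSet needs at least one shot")
        n0 = self.shots[0][0].n
        dt0 = self.shots[0][0].dt
        for gx, gy in self.shots:
            if gx.n != n0 or gy.n != n0 or gx.dt != dt0 or gy.dt != dt0:
                raise ValueError("all shots must share dt and length")

    @property
    def n_shots(self) -> int:
        return len(self.shots)

    @property
    def dt(self) -> float:
        return self.shots[0][0].dt

    @property
    def n_samples(self) -> int:
        return self.shots[0][0].n
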