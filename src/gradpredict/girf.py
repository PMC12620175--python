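"""Gradient impulse response function (GIRF) estimation and prediction.

The GIRF / gradient system transfer function is the linear-time-invariant
characterization of the gradient chain: a complex transfer function H(f) on
a uniform frequency grid, estimated from nominal-input / measured-output
waveform pairs by regularized frequency-domain least squares

    H(f) = sum_n conj(I_n(f)) O_n(f) / (sum_n |I_n(f)|^2 + lam * max_f sum_n |I_n(f)|^2)

where I_n, O_n are zero-padded FFTs of the n-th nominal and measured
waveform.  Prediction applies H by frequency-domain multiplication.  All
transforms use an FFT length of at least twice the longest training
waveform, so the convolution is linear rather than circular.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import next_fast_len

from .core import GradientWaveform, WaveformPair


@dataclass
class GIRFModel:
    """Per-axis regularized complex transfer function on a frequency grid."""

    axis: str
    transfer_function: np.ndarray  # complex, length fft_length
    fft_length: int
    regularization: float
    dt: float

    @property
    def freqs(self) -> np.ndarray:
        """Frequency grid in Hz (numpy fftfreq ordering)."""
        return np.fft.fftfreq(self.fft_length, self.dt)

    def impulse_response(self) -> np.ndarray:
        """Real time-domain impulse response."""
        h = np.fft.ifft(self.transfer_function)
        if np.max(np.abs(h.imag)) > 1e-10 * np.max(np.abs(h.real)):
            raise ValueError("transfer function is not conjugate-symmetric")
        return h.real


def estimate_girf(
    pairs: list[WaveformPair],
    regularization: float = 1e-9,
    fft_length: int | None = None,
) -> GIRFModel:
    """Estimate a GIRF from nominal/measured pairs of one axis.

    All training pairs (every shape at every amplitude) are pooled into a
    single per-axis estimate.
    """
    if not pairs:
        raise ValueError("need at least one waveform pair")
    dt = pairs[0].nominal.dt
    axis = pairs[0].nominal.axis
    for p in pairs:
        if p.measured is None:
            raise ValueError("all pairs must carry a measured waveform")
        if abs(p.nominal.dt - dt) > 1e-9 * dt or p.nominal.axis != axis:
            raise ValueError("all pairs must share dt and axis")
    max_len = max(p.nominal.n for p in pairs)
    if fft_length is None:
        fft_length = next_fast_len(2 * max_len)
    elif fft_length < 2 * max_len:
        raise ValueError("fft_length must be >= 2x the longest training waveform")
    num = np.zeros(fft_length, dtype=complex)
    den = np.zeros(fft_length)
    for p in pairs:
        i_f = np.fft.fft(p.nominal.samples, fft_length)
        o_f = np.fft.fft(p.measured.samples, fft_length)
        num += np.conj(i_f) * o_f
        den += np.abs(i_f) ** 2
    if den.max() == 0:
        raise ValueError("zero-energy input set")
    h = num / (den + regularization * den.max())
    return GIRFModel(
        axis=axis,
        transfer_function=h,
        fft_length=fft_length,
        regularization=regularization,
        dt=dt,
    )


def predict_with_girf(
    girf: GIRFModel, nominal: GradientWaveform
) -> GradientWaveform:
    """Predict the played-out waveform by applying H(f) to the nominal one."""
    if nominal.dt != girf.dt:
        raise ValueError("waveform dt does not match the GIRF raster")
    if nominal.n > girf.fft_length:
        raise ValueError("waveform longer than the GIRF FFT length")
    spec = np.fft.fft(nominal.samples, girf.fft_length)
    out = np.fft.ifft(spec * girf.transfer_function).real[: nominal.n]
    return nominal.with_samples(out)
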