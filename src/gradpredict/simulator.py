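"""Synthetic nonlinear gradient-system simulator.

Stands in for a physical gradient chain: given a nominal waveform it produces
a "measured" waveform carrying the distortion phenomenology of real
amplifiers and coils — a band-limited, delayed linear core with exponential
eddy-current terms, zero-crossing (crossover) dead-zone distortion,
amplitude-dependent gain and delay, slew-rate limiting, and additive
measurement noise.

The functional forms are synthetic stand-ins chosen to reproduce the
qualitative behavior of a push-pull gradient amplifier; they are not fits to
any particular scanner.  With the nonlinear parameters zeroed the chain is
exactly linear time-invariant, which is the regime where GIRF prediction is
near-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .core import GradientWaveform, Library, WaveformPair
from .waveforms import SYSTEM_MAX_GRAD, SYSTEM_SLEW


@dataclass
class GradientSystemModel:
    """Parameters of the simulated gradient chain for one axis.

    With ``crossover_deadzone = amp_gain_slope = 0``, ``amp_delay_slope = 0``
    and ``slew_limit = inf`` the system is exactly LTI.
    """

    group_delay: float = 20e-6  # s
    lowpass_cutoff: float = 20e3  # Hz
    eddy_terms: tuple[tuple[float, float], ...] = ((0.003, 100e-6), (0.001, 1e-3))
    crossover_deadzone: float = 2.0  # mT/m
    amp_gain_slope: float = 0.05  # dimensionless
    amp_delay_slope: float = 16e-6  # s
    slew_limit: float = SYSTEM_SLEW  # T/m/s
    noise_sigma: float = 0.05  # mT/m
    reference_amp: float = SYSTEM_MAX_GRAD  # mT/m
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.crossover_deadzone < 0 or self.noise_sigma < 0:
            raise ValueError("deadzone and noise sigma must be non-negative")
        for coupling, tau in self.eddy_terms:
            if tau <= 0:
                raise ValueError("eddy time constants must be positive")
        if self.slew_limit <= 0:
            raise ValueError("slew_limit must be positive")

    def lti_limit(self) -> "GradientSystemModel":
        """Copy with all nonlinear terms and noise switched off."""
        return replace(
            self,
            crossover_deadzone=0.0,
            amp_gain_slope=0.0,
            amp_delay_slope=0.0,
            slew_limit=np.inf,
            noise_sigma=0.0,
        )


def per_axis_models(
    base: GradientSystemModel | None = None, seed: int = 0
) -> dict[str, GradientSystemModel]:
    """Slightly different default parameter sets per physical axis.

    Real gradient axes differ (coil geometry, amplifier channels), so each
    axis gets its own mild perturbation of the base parameters.
    """
    base = base or GradientSystemModel()
    tweaks = {
        "x": dict(group_delay=base.group_delay * 1.1, crossover_deadzone=base.crossover_deadzone * 0.9),
        "y": dict(group_delay=base.group_delay * 0.9, amp_gain_slope=base.amp_gain_slope * 1.2),
        "z": dict(),
    }
    out = {}
    for i, axis in enumerate(("x", "y", "z")):
        out[axis] = replace(base, rng_seed=seed + i, **tweaks[axis])
    return out


def _fractional_delay(x: np.ndarray, delay_samples: float) -> np.ndarray:
    """Causal fractional delay: integer shift + first-order (linear)
    interpolation, with zero extension at the start.

    Strictly causal by construction (a band-limited sinc interpolator would
    ring ahead of the delay); the mild high-frequency roll-off of linear
    interpolation folds into the simulated system's band limitation.
    """
    if delay_samples == 0:
        return x.copy()
    if delay_samples < 0:
        raise ValueError("only non-negative delays are supported")
    n = x.size
    di = int(np.floor(delay_samples))
    frac = delay_samples - di
    a = np.zeros_like(x)
    if di < n:
        a[di:] = x[: n - di]
    if frac == 0:
        return a
    b = np.zeros_like(x)
    if di + 1 < n:
        b[di + 1 :] = x[: n - di - 1]
    return (1.0 - frac) * a + frac * b


def apply_linear_response(
    model: GradientSystemModel, w: GradientWaveform
) -> GradientWaveform:
    """Linear stage: causal low-pass + group delay − eddy-current terms.

    The eddy-current contribution is ``sum_j c_j * (dG/dt (*) exp(-t/tau_j)) dt``
    evaluated with a causal first-order IIR recursion, i.e. decaying
    exponential fields driven by the gradient switching rate.
    """
    x = w.samples
    dt = w.dt
    nyq = 1.0 / (2 * dt)
    y = x
    if np.isfinite(model.lowpass_cutoff) and model.lowpass_cutoff < nyq:
        b, a = sps.butter(3, model.lowpass_cutoff / nyq)
        y = sps.lfilter(b, a, y)
    y = _fractional_delay(y, model.group_delay / dt)
    dxdt = np.gradient(x, dt)
    eddy = np.zeros_like(x)
    for coupling, tau in model.eddy_terms:
        alpha = np.exp(-dt / tau)
        # y_e[n] = alpha*y_e[n-1] + dxdt[n]; scaled by dt => discrete conv
        resp = sps.lfilter([1.0], [1.0, -alpha], dxdt) * dt
        eddy += coupling * resp
    y = y - _fractional_delay(eddy, model.group_delay / dt)
    return w.with_samples(y)


def apply_crossover_distortion(
    model: GradientSystemModel, w: GradientWaveform
) -> GradientWaveform:
    """Dead-zone around zero: y = sign(x) * max(|x| - delta, 0)."""
    d = model.crossover_deadzone
    x = w.samples
    return w.with_samples(np.sign(x) * np.maximum(np.abs(x) - d, 0.0))


def apply_amplitude_dependence(
    model: GradientSystemModel, w: GradientWaveform
) -> GradientWaveform:
    """Amplitude-dependent gain and delay.

    gain(A) = 1 - g_A (1 - |A|/A_sys); extra delay tau(A) = tau_A (1 - |A|/A_sys);
    identity at A = A_sys.  Gain and delay increase as |A| decreases,
    mimicking the weaker response of push-pull stages at low drive.
    """
    a = w.amp_scale
    if a == 0:
        raise ValueError("waveform amp_scale must be nonzero")
    if abs(a) > model.reference_amp * (1 + 1e-9):
        raise ValueError("amp_scale exceeds the system reference amplitude")
    frac = 1.0 - abs(a) / model.reference_amp
    gain = 1.0 - model.amp_gain_slope * frac
    delay = model.amp_delay_slope * frac
    y = gain * _fractional_delay(w.samples, delay / w.dt)
    return w.with_samples(y)


def apply_slew_limit(
    model: GradientSystemModel, w: GradientWaveform
) -> GradientWaveform:
    """Rate limiter: y[n] = y[n-1] + clip(x[n] - y[n-1], +-slew*dt)."""
    if not np.isfinite(model.slew_limit):
        return w.with_samples(w.samples.copy())
    step = model.slew_limit * w.dt * 1e3  # mT/m per raster
    x = w.samples
    y = np.empty_like(x)
    prev = min(max(x[0], -step), step)
    y[0] = prev
    for n in range(1, x.size):
        d = x[n] - prev
        if d > step:
            prev = prev + step
        elif d < -step:
            prev = prev - step
        else:
            prev = x[n]  # exact: no floating-point drift when feasible
        y[n] = prev
    return w.with_samples(y)


def simulate_measurement(
    model: GradientSystemModel,
    w: GradientWaveform,
    add_noise: bool = True,
    seed: int | None = None,
) -> GradientWaveform:
    """Full distortion chain: linear -> amplitude -> crossover -> slew (+noise).

    Deterministic for a given seed (defaults to ``model.rng_seed``).
    """
    out = apply_linear_response(model, w)
    if (model.amp_gain_slope != 0 or model.amp_delay_slope != 0) and w.amp_scale != 0:
        out = apply_amplitude_dependence(model, out)
    out = apply_crossover_distortion(model, out)
    out = apply_slew_limit(model, out)
    if add_noise and model.noise_sigma > 0:
        rng = np.random.default_rng(model.rng_seed if seed is None else seed)
        out = out.with_samples(
            out.samples + rng.normal(0.0, model.noise_sigma, out.n)
        )
    return out


def simulate_library(
    models: GradientSystemModel | dict[str, GradientSystemModel],
    library: Library,
    add_noise: bool = True,
    seed: int | None = None,
) -> Library:
    """Attach a simulated measured partner to every nominal waveform.

    Per-waveform noise seeds are spawned deterministically from ``seed`` (or
    the per-axis model seed), so the paired library is reproducible.
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    pairs: list[WaveformPair] = []
    base_seed = seed
    for i, p in enumerate(library):
        axis = p.nominal.axis
        model = models[axis] if isinstance(models, dict) else models
        s = (model.rng_seed if base_seed is None else base_seed) * 1000003 + i
        meas = simulate_measurement(model, p.nominal, add_noise=add_noise, seed=s % (2**31))
        pairs.append(WaveformPair(nominal=p.nominal, measured=meas, split=p.split))
    return Library(pairs)
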