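"""Nominal gradient waveform design.

Two waveform families live here:

* system-characterization waveforms (trapezoids, triangle trains, chirps,
  multisines) used to probe the gradient chain over a grid of amplitudes, and
* imaging readouts (multi-shot spiral-in-out and rosette trajectories) whose
  gradients are obtained from analytic k-space parametrizations.

All generated waveforms start and end at zero amplitude and respect a
configured slew-rate limit; readout parametrizations are time-warped with a
trapezoidal speed profile so the gradients ramp smoothly from and to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    AXES,
    DEFAULT_DT,
    GAMMA_BAR,
    GradientWaveform,
    Library,
    ShotSet,
    WaveformPair,
    signed_peak,
)

# Scanner-class system limits (7T small-animal gradient insert):
# 770 mT/m maximum amplitude reached in a 146 us rise time.
SYSTEM_MAX_GRAD = 770.0  # mT/m
SYSTEM_SLEW = 770e-3 / 146e-6  # T/m/s ~= 5274


def make_trapezoid(
    plateau_amp: float,
    plateau_dur: float,
    ramp_dur: float,
    dt: float = DEFAULT_DT,
    axis: str = "z",
    label: str = "trapezoid",
) -> GradientWaveform:
    """Trapezoidal gradient lobe: linear ramp up, plateau, linear ramp down.

    Area under the waveform is ``plateau_amp * (plateau_dur + ramp_dur)``
    (the two half-ramps contribute one full ramp duration).
    """
    if plateau_dur < 0 or ramp_dur < 0:
        raise ValueError("durations must be non-negative")
    if ramp_dur < dt:
        raise ValueError("ramp_dur must be at least one raster interval")
    n_ramp = max(1, int(round(ramp_dur / dt)))
    n_plat = int(round(plateau_dur / dt))
    up = plateau_amp * np.arange(n_ramp + 1) / n_ramp
    plat = np.full(n_plat, plateau_amp)
    down = up[::-1][1:]
    samples = np.concatenate([up, plat, down])
    return GradientWaveform(samples, dt, axis=axis, amp_scale=plateau_amp, label=label)


def make_triangle_train(
    peak_amp: float,
    n_triangles: int,
    ramp_dur: float,
    dt: float = DEFAULT_DT,
    axis: str = "z",
    label: str = "triangle_train",
) -> GradientWaveform:
    """Train of alternating-sign triangles (zero-mean for even counts)."""
    if n_triangles < 1:
        raise ValueError("n_triangles must be >= 1")
    if ramp_dur < dt:
        raise ValueError("ramp_dur must be at least one raster interval")
    n_ramp = max(1, int(round(ramp_dur / dt)))
    up = np.arange(n_ramp + 1) / n_ramp
    tri = np.concatenate([up, up[::-1][1:]])  # 0 -> 1 -> 0
    parts = [np.zeros(1)]
    for i in range(n_triangles):
        sign = 1.0 if i % 2 == 0 else -1.0
        parts.append(sign * peak_amp * tri[1:])  # skip duplicated zero sample
    samples = np.concatenate(parts)
    return GradientWaveform(samples, dt, axis=axis, amp_scale=peak_amp, label=label)


def make_chirp(
    f_start: float,
    f_end: float,
    duration: float,
    peak_amp: float,
    slew_limit: float = SYSTEM_SLEW,
    dt: float = DEFAULT_DT,
    axis: str = "z",
    label: str = "chirp",
) -> GradientWaveform:
    """Linear-frequency sweep with a slew-constrained envelope.

    The instantaneous amplitude of a sinusoid at frequency f is slew-limited
    to ``slew_limit / (2 pi f)``; the envelope is the pointwise minimum of
    ``peak_amp`` and that bound (with a small safety margin), smoothed so the
    envelope derivative stays negligible, and faded to zero at the end.
    """
    if not (0 <= f_start < f_end):
        raise ValueError("need 0 <= f_start < f_end")
    if duration <= 0:
        raise ValueError("duration must be positive")
    nyquist = 1.0 / (2.0 * dt)
    if f_end >= nyquist:
        raise ValueError(f"f_end {f_end} Hz at or above Nyquist {nyquist} Hz")
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    finst = f_start + (f_end - f_start) * t / duration
    phase = 2 * np.pi * (f_start * t + 0.5 * (f_end - f_start) * t**2 / duration)
    if peak_amp == 0:
        return GradientWaveform(
            np.zeros(n), dt, axis=axis, amp_scale=0.0, label=label
        )
    # slew bound for a pure sinusoid, with margin for envelope slope terms
    margin = 0.85
    with np.errstate(divide="ignore"):
        bound = margin * slew_limit * 1e3 / (2 * np.pi * np.maximum(finst, 1.0))
    env = np.minimum(abs(peak_amp), bound)
    # smooth the envelope so env' stays small
    n_sm = max(3, int(round(5e-5 / dt)))
    kernel = np.hanning(n_sm)
    kernel /= kernel.sum()
    env = np.convolve(env, kernel, mode="same")
    g = np.sign(peak_amp) * env * np.sin(phase)
    # slew-aware end fade: slope budget 12% of the slew limit
    a_tail = np.max(np.abs(g[-max(1, n // 4) :]))
    fade_dur = a_tail * 1e-3 * (np.pi / 2) / (0.12 * slew_limit)
    n_fade = int(np.clip(np.ceil(fade_dur / dt), 8, n // 3))
    g = g * _end_fade(n, n_fade)
    # guarantee the numeric slew bound (shrink globally if margin insufficient)
    for _ in range(8):
        s = np.max(np.abs(np.diff(g))) * 1e-3 / dt
        if s <= slew_limit:
            break
        g *= slew_limit / s
    return GradientWaveform(g, dt, axis=axis, amp_scale=signed_peak(g), label=label)


def make_multisine(
    freqs: list[float],
    amps: list[float],
    duration: float,
    dt: float = DEFAULT_DT,
    axis: str = "z",
    label: str = "multisine",
) -> GradientWaveform:
    """Sum of sinusoids rescaled so the peak equals the largest |amplitude|."""
    freqs = np.asarray(freqs, dtype=float)
    amps = np.asarray(amps, dtype=float)
    if freqs.size == 0:
        raise ValueError("need at least one frequency")
    if freqs.size != amps.size:
        raise ValueError("freqs and amps must have equal length")
    nyquist = 1.0 / (2.0 * dt)
    if np.any(freqs >= nyquist):
        raise ValueError("all frequencies must be below Nyquist")
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    g = np.zeros(n)
    for f, a in zip(freqs, amps):
        g += a * np.sin(2 * np.pi * f * t)
    g *= _end_fade(n, max(16, n // 4))
    target = np.max(np.abs(amps))
    peak = np.max(np.abs(g))
    if target > 0 and peak > 0:
        g *= target / peak
    return GradientWaveform(g, dt, axis=axis, amp_scale=signed_peak(g), label=label)


def _end_fade(n: int, n_fade: int | None = None) -> np.ndarray:
    """Half-cosine taper bringing the final sample exactly to zero."""
    if n_fade is None:
        n_fade = max(8, n // 50)
    n_fade = min(n_fade, n - 1)
    fade = np.ones(n)
    fade[-n_fade:] = 0.5 * (1 + np.cos(np.pi * np.arange(1, n_fade + 1) / n_fade))
    return fade


def _speed_profile(n: int, ramp_frac: float = 0.08) -> np.ndarray:
    """Normalized arc-length schedule lam[0..n-1] in [0, 1].

    Trapezoidal speed: cosine-smoothed ramp up over ``ramp_frac`` of the
    samples, constant, ramp down.  lam'(0) = lam'(end) = 0, so gradients
    derived as dk/dt start and end at zero.
    """
    nr = max(2, int(round(ramp_frac * n)))
    speed = np.ones(n)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
    speed[:nr] = ramp
    speed[-nr:] = ramp[::-1]
    lam = np.concatenate([[0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1]))])
    return lam / lam[-1]


def _speed_profile_rate(n: int, dt: float, ramp_frac: float = 0.08) -> np.ndarray:
    """d(lam)/dt corresponding to :func:`_speed_profile` (length n)."""
    nr = max(2, int(round(ramp_frac * n)))
    speed = np.ones(n)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
    speed[:nr] = ramp
    speed[-nr:] = ramp[::-1]
    total = np.concatenate([[0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1]))])[-1]
    return speed / (total * dt)


def _gradients_from_k(kx: np.ndarray, ky: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradients (mT/m) from a k-space path in cycles/m."""
    gx = np.gradient(kx, dt) / GAMMA_BAR * 1e3
    gy = np.gradient(ky, dt) / GAMMA_BAR * 1e3
    return gx, gy


def _prephaser_shape(
    area_ref: float, max_grad: float, slew: float, dt: float
) -> np.ndarray:
    """Unit-area trapezoid (per s) able to carry areas up to area_ref T*s/m.

    All shots share this timing; per-shot areas scale the amplitude only,
    so every shot has the same prephaser duration.
    """
    gmax = 0.9 * max_grad * 1e-3  # T/m
    s = 0.9 * slew
    if area_ref <= gmax**2 / s:  # triangle suffices
        ramp = np.sqrt(area_ref / s)
        plat = 0.0
    else:
        ramp = gmax / s
        plat = area_ref / gmax - ramp
    n_ramp = max(1, int(np.ceil(ramp / dt)))
    n_plat = int(np.ceil(plat / dt))
    up = np.arange(n_ramp + 1) / n_ramp
    shape = np.concatenate([up, np.ones(n_plat), up[::-1][1:]])
    return shape / np.trapezoid(shape, dx=dt)


def make_spiral_inout(
    n_shots: int,
    fov: float,
    resolution: float,
    max_grad: float = SYSTEM_MAX_GRAD,
    slew_limit: float = SYSTEM_SLEW,
    dt: float = DEFAULT_DT,
    prephaser: bool = True,
    rotation: str = "uniform",
) -> ShotSet:
    """Multi-shot Archimedean spiral-in-out readout.

    Each shot traverses an Archimedean spiral from the k-space edge to the
    center and back out on the opposite side, passing through k = 0 at the
    echo center (midpoint of the readout).  Shot m is rotated by
    ``2 pi m / n_shots`` (uniform) or by the golden angle.  When
    ``prephaser`` is set, a trapezoid pair moves k from the origin to the
    spiral-in starting point.
    """
    if n_shots < 1:
        raise ValueError("n_shots must be >= 1")
    if resolution > fov:
        raise ValueError("resolution cannot exceed fov")
    if rotation not in ("uniform", "golden"):
        raise ValueError("rotation must be 'uniform' or 'golden'")
    if max_grad <= 0:
        raise ValueError("spiral design infeasible: max_grad must be positive")
    if slew_limit <= 0:
        raise ValueError("spiral design infeasible: slew_limit must be positive")
    k_max = 1.0 / (2.0 * resolution)
    n_turns = k_max * fov / n_shots  # turns per interleaf (Nyquist)

    # choose the readout duration from the amplitude and slew constraints
    lam = np.linspace(0, 1, 4096)
    k_path = _spiral_inout_path(lam, k_max, n_turns, 0.0)
    v = np.abs(np.gradient(k_path, lam))  # |dk/dlam|
    a = np.abs(np.gradient(np.gradient(k_path, lam), lam))
    # mid-profile speed exceeds 1/T by ~1/(1-ramp_frac)
    boost = 1.1
    t_amp = boost * v.max() / (0.95 * GAMMA_BAR * max_grad * 1e-3)
    t_slew = boost * np.sqrt(a.max() / (0.95 * GAMMA_BAR * slew_limit))
    duration = max(t_amp, t_slew)
    # refine: lengthen until the sampled design respects both limits
    for _ in range(30):
        n = int(np.ceil(duration / dt))
        if n % 2:
            n += 1
        n += 1  # odd sample count: exact midpoint sample at k = 0
        lam_t = _speed_profile(n)
        kp = _spiral_inout_path(lam_t, k_max, n_turns, 0.0)
        gx0, gy0 = _gradients_from_k(kp.real, kp.imag, dt)
        gc = gx0 + 1j * gy0
        # vector amplitude/slew bound every per-axis value for any rotation
        amp = np.max(np.abs(gc))
        slew = np.max(np.abs(np.diff(gc))) * 1e-3 / dt
        ratio = max(amp / (0.98 * max_grad), np.sqrt(slew / (0.98 * slew_limit)))
        if ratio <= 1.0:
            break
        duration *= 1.02 * ratio

    shots = []
    adc_start = 0
    pre_shape = (
        _prephaser_shape(k_max / GAMMA_BAR, max_grad, slew_limit, dt)
        if prephaser
        else None
    )
    for m in range(n_shots):
        if rotation == "uniform":
            phi = 2 * np.pi * m / n_shots
        else:
            phi = np.pi * (3 - np.sqrt(5)) * m
        k_path = _spiral_inout_path(lam_t, k_max, n_turns, phi)
        kx, ky = k_path.real, k_path.imag
        gx, gy = _gradients_from_k(kx, ky, dt)
        echo = n // 2
        if prephaser:
            # move k from the origin to the spiral-in start
            px = pre_shape * (kx[0] / GAMMA_BAR) * 1e3
            py = pre_shape * (ky[0] / GAMMA_BAR) * 1e3
            gx = np.concatenate([px, gx])
            gy = np.concatenate([py, gy])
            echo += px.size
            adc_start = px.size
        for g in (gx, gy):
            s = np.max(np.abs(np.diff(g))) * 1e-3 / dt
            if s > slew_limit:
                raise ValueError(
                    f"spiral design infeasible: numeric slew {s:.0f} exceeds "
                    f"slew_limit {slew_limit:.0f} T/m/s"
                )
            if np.max(np.abs(g)) > max_grad * (1 + 1e-9):
                raise ValueError(
                    f"spiral design infeasible: amplitude {np.max(np.abs(g)):.1f} "
                    f"exceeds max_grad {max_grad:.1f} mT/m"
                )
        wx = GradientWaveform(gx, dt, axis="x", label=f"spiral_inout_shot{m}_x")
        wy = GradientWaveform(gy, dt, axis="y", label=f"spiral_inout_shot{m}_y")
        shots.append((wx, wy))
    return ShotSet(
        shots,
        readout_duration=n * dt,
        echo_index=echo,
        adc_start=adc_start,
        k_max=k_max,
        fov=fov,
        label="spiral_inout",
    )


def _spiral_inout_path(
    lam: np.ndarray, k_max: float, n_turns: float, phi: float
) -> np.ndarray:
    """Complex k(lam) for the spiral-in-out: edge -> center -> opposite edge."""
    k = np.empty(lam.shape, dtype=complex)
    first = lam <= 0.5
    u_in = 1.0 - 2.0 * lam[first]
    k[first] = k_max * u_in * np.exp(1j * (phi + 2 * np.pi * n_turns * u_in))
    u_out = 2.0 * lam[~first] - 1.0
    k[~first] = k_max * u_out * np.exp(
        1j * (phi + np.pi - 2 * np.pi * n_turns * u_out)
    )
    return k


def make_rosette(
    n_shots: int,
    n_petals: int,
    fov: float,
    resolution: float,
    readout_duration: float,
    dt: float = DEFAULT_DT,
) -> ShotSet:
    """Multi-shot rosette readout.

    Analytic form per shot (before the end-ramp time warp):
    ``k(t) = k_max sin(w1 t) [cos(w2 t + phi_m), sin(w2 t + phi_m)]`` with
    ``w2/w1 = (n_petals - 1)/n_petals`` and ``w1 T = n_petals pi`` so the shot
    traces ``n_petals`` petals and k(0) = k(T) = 0.  Shot rotations phi_m are
    uniform over 2 pi.  Gradients are computed analytically (chain rule
    through the time warp).
    """
    if n_petals < 2:
        raise ValueError("n_petals must be >= 2")
    if n_shots < 1:
        raise ValueError("n_shots must be >= 1")
    n_float = readout_duration / dt
    n = int(round(n_float))
    if abs(n_float - n) > 1e-6:
        raise ValueError("readout_duration must be an integer number of rasters")
    k_max = 1.0 / (2.0 * resolution)
    lam = _speed_profile(n)
    dlam_dt = _speed_profile_rate(n, dt)
    # angular arguments as functions of lam in [0, 1]
    a1 = np.pi * n_petals * lam
    a2 = np.pi * (n_petals - 1) * lam
    d_a1 = np.pi * n_petals * dlam_dt
    d_a2 = np.pi * (n_petals - 1) * dlam_dt
    shots = []
    for m in range(n_shots):
        phi = 2 * np.pi * m / n_shots
        c2, s2 = np.cos(a2 + phi), np.sin(a2 + phi)
        s1, c1 = np.sin(a1), np.cos(a1)
        kx = k_max * s1 * c2
        ky = k_max * s1 * s2
        dkx = k_max * (c1 * d_a1 * c2 - s1 * s2 * d_a2)
        dky = k_max * (c1 * d_a1 * s2 + s1 * c2 * d_a2)
        gx = dkx / GAMMA_BAR * 1e3
        gy = dky / GAMMA_BAR * 1e3
        wx = GradientWaveform(gx, dt, axis="x", label=f"rosette_shot{m}_x")
        wy = GradientWaveform(gy, dt, axis="y", label=f"rosette_shot{m}_y")
        shots.append((wx, wy))
    # the echo (a k = 0 crossing) closest to the readout midpoint
    zeros = np.where(np.isclose(np.sin(a1), 0, atol=1e-9))[0]
    interior = zeros[(zeros > 0) & (zeros < n - 1)]
    echo = int(interior[np.argmin(np.abs(interior - n // 2))]) if interior.size else n // 2
    return ShotSet(
        shots,
        readout_duration=readout_duration,
        echo_index=echo,
        k_max=k_max,
        fov=fov,
        label="rosette",
    )


def scale_to_amplitudes(
    w: GradientWaveform,
    amplitudes: list[float],
    system_max: float = SYSTEM_MAX_GRAD,
) -> list[GradientWaveform]:
    """Rescale a waveform to each requested signed peak amplitude."""
    if w.amp_scale == 0:
        raise ValueError("cannot rescale a zero waveform")
    out = []
    for a in amplitudes:
        if a == 0:
            raise ValueError("amplitudes must be nonzero")
        if abs(a) > system_max:
            warnings.warn(
                f"amplitude {a} mT/m exceeds system maximum {system_max} mT/m",
                stacklevel=2,
            )
        scaled = w.samples * (a / w.amp_scale)
        out.append(
            GradientWaveform(scaled, w.dt, axis=w.axis, amp_scale=a, label=w.label)
        )
    return out


@dataclass
class LibraryConfig:
    """Configuration of the characterization/validation waveform library.

    The default configuration contains 18 distinct waveform shapes, 11 in the
    training split at 15 amplitudes uniformly covering [70, 700] mT/m and 7
    in the validation split at 7 amplitudes over the same range, replicated
    on each requested axis.
    """

    dt: float = DEFAULT_DT
    axes: tuple[str, ...] = AXES
    train_amplitudes: tuple[float, ...] = tuple(np.linspace(70.0, 700.0, 15))
    val_amplitudes: tuple[float, ...] = tuple(np.linspace(70.0, 700.0, 7))
    duration_scale: float = 1.0  # stretches chirp/multisine durations
    tail_padding: float = 1.0e-3  # s of zeros after each waveform: the
    # measurement window extends past the gradient event so eddy-current
    # decay tails are captured rather than truncated
    slew_limit: float = SYSTEM_SLEW
    system_max: float = SYSTEM_MAX_GRAD
    seed: int = 0


def _unit_shapes(cfg: LibraryConfig) -> dict[str, tuple[str, GradientWaveform]]:
    """The 18 default waveform shapes at the 100 mT/m working amplitude.

    Returns label -> (split, waveform).  Training shapes are predominantly
    system-characterization waveforms; validation shapes are predominantly
    imaging-type waveforms, mirroring the characterization-library design.

    Every shape is designed against an effective slew limit scaled by
    (working amplitude / max library amplitude) so that rescaling to the top
    of the amplitude grid remains slew-feasible on the modeled hardware.
    """
    dt = cfg.dt
    ds = cfg.duration_scale
    a_top = max(abs(a) for a in (*cfg.train_amplitudes, *cfg.val_amplitudes))
    work = 100.0
    sl_eff = cfg.slew_limit * work / a_top  # slew budget at working amplitude

    # feasible ramp for trapezoids/triangles at the top amplitude
    ramp = max(dt, np.ceil(work * 1e-3 / sl_eff / dt) * dt) * 1.05
    ramp = np.ceil(ramp / dt) * dt

    def budget_ok(w: GradientWaveform) -> tuple[bool, float]:
        # slew when rescaled so the waveform's own peak reaches a_top
        peak = np.max(np.abs(w.samples))
        allowed = cfg.slew_limit * peak / a_top
        s = w.numeric_slew().max()
        return s <= 0.999 * allowed, s / allowed

    def chirp(f0, f1, dur, label):
        # designed against the amplitude-scaled slew budget at the working
        # amplitude; high-amplitude rescales of a slew-constrained chirp are
        # intentionally demanding and may engage the amplifier's rate limiter
        return make_chirp(f0, f1, dur * ds, work, slew_limit=sl_eff, dt=dt, label=label)

    def msine(freqs, label):
        # amplitudes roll off as 1/f (equal slew demand per tone); the first
        # tone stays pinned at the working amplitude so lowering the corner
        # frequency genuinely reduces the slew-to-peak ratio
        f_corner = sl_eff * 1e3 / (2 * np.pi * work) / 2.5
        for _ in range(12):
            rel = [min(1.0, f_corner / f) for f in freqs]
            amps = [work * r / rel[0] for r in rel]
            w = make_multisine(freqs, amps, 2.0e-3 * ds, dt=dt, label=label)
            ok, ratio = budget_ok(w)
            if ok:
                break
            f_corner *= 0.9 / ratio
        return w

    # library spiral: per-axis peak is below the vector amplitude, so the
    # slew budget (referenced to the per-axis peak at the top amplitude)
    # needs iterative tightening
    sl_sp = cfg.slew_limit * 140.0 / a_top
    for _ in range(10):
        spiral = make_spiral_inout(
            16, 0.03, 1.0e-3, max_grad=140.0, slew_limit=sl_sp, dt=dt, prephaser=False
        )
        checks = [budget_ok(w) for w in spiral.shots[0]]
        if all(ok for ok, _ in checks):
            break
        sl_sp *= 0.9 / max(r for _, r in checks)
    rosette = make_rosette(8, 5, 0.03, 0.6e-3, 5.0e-3, dt=dt)

    def relabel(w, label):
        return w.with_samples(w.samples, label=label)

    shapes: dict[str, tuple[str, GradientWaveform]] = {}
    # --- training split: characterization waveforms + one readout shape
    shapes["trapezoid_wide"] = (
        "train",
        make_trapezoid(work, 0.8e-3, ramp, dt, label="trapezoid_wide"),
    )
    shapes["trapezoid_narrow"] = (
        "train",
        make_trapezoid(work, 0.3e-3, ramp, dt, label="trapezoid_narrow"),
    )
    shapes["trapezoid_bipolar"] = ("train", _bipolar_trapezoid(cfg, ramp))
    shapes["triangle_train_4"] = (
        "train",
        make_triangle_train(work, 4, ramp, dt, label="triangle_train_4"),
    )
    shapes["triangle_train_8"] = (
        "train",
        make_triangle_train(work, 8, ramp, dt, label="triangle_train_8"),
    )
    shapes["chirp_slow"] = ("train", chirp(0.0, 5e3, 2.0e-3, "chirp_slow"))
    shapes["chirp_fast"] = ("train", chirp(0.0, 15e3, 2.0e-3, "chirp_fast"))
    shapes["multisine_low"] = ("train", msine([400.0, 900.0, 1400.0], "multisine_low"))
    shapes["multisine_mid"] = ("train", msine([500.0, 1800.0, 3300.0], "multisine_mid"))
    shapes["multisine_high"] = (
        "train",
        msine([600.0, 2900.0, 6100.0], "multisine_high"),
    )
    shapes["spiral_train_x"] = (
        "train",
        relabel(spiral.shots[0][0], "spiral_train_x"),
    )
    # --- validation split: predominantly imaging waveforms
    shapes["spiral_val_y"] = ("validation", relabel(spiral.shots[0][1], "spiral_val_y"))
    shapes["rosette_val_x"] = ("validation", relabel(rosette.shots[1][0], "rosette_val_x"))
    shapes["rosette_val_y"] = ("validation", relabel(rosette.shots[1][1], "rosette_val_y"))
    shapes["trapezoid_val"] = (
        "validation",
        make_trapezoid(work, 0.6e-3, ramp, dt, label="trapezoid_val"),
    )
    shapes["chirp_val"] = ("validation", chirp(0.0, 10e3, 2.0e-3, "chirp_val"))
    shapes["multisine_val"] = (
        "validation",
        msine([450.0, 2300.0, 4700.0], "multisine_val"),
    )
    shapes["triangle_train_6"] = (
        "validation",
        make_triangle_train(work, 6, ramp, dt, label="triangle_train_6"),
    )
    return shapes


def _bipolar_trapezoid(cfg: LibraryConfig, ramp: float) -> GradientWaveform:
    pos = make_trapezoid(100.0, 0.4e-3, ramp, cfg.dt)
    samples = np.concatenate([pos.samples, -pos.samples[1:]])
    return GradientWaveform(
        samples, cfg.dt, amp_scale=100.0, label="trapezoid_bipolar"
    )


def build_characterization_library(cfg: LibraryConfig | None = None) -> Library:
    """Build the default 18-shape nominal library with train/validation split.

    Per axis: 11 training shapes x len(train_amplitudes) + 7 validation
    shapes x len(val_amplitudes) nominal waveforms (214 with the defaults).
    Deterministic for a given configuration.
    """
    cfg = cfg or LibraryConfig()
    shapes = _unit_shapes(cfg)
    labels = list(shapes)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate waveform labels in library config")
    n_tail = int(round(cfg.tail_padding / cfg.dt))
    pairs: list[WaveformPair] = []
    for axis in cfg.axes:
        for label, (split, proto) in shapes.items():
            amps = cfg.train_amplitudes if split == "train" else cfg.val_amplitudes
            samples = np.concatenate([proto.samples, np.zeros(n_tail)])
            base = GradientWaveform(
                samples, cfg.dt, axis=axis, amp_scale=proto.amp_scale, label=label
            )
            for w in scale_to_amplitudes(base, list(amps), cfg.system_max):
                pairs.append(WaveformPair(nominal=w, split=split))
    return Library(pairs)
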