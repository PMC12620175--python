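# Methods

`gradpredict` models the temporal response of an MRI gradient chain and
propagates that model through non-Cartesian image reconstruction and
diffusion tensor mapping.  This note records the models, their
assumptions, the defaults and why they were chosen, and what the synthetic
experiments do and do not demonstrate.

## The problem

A pulse sequence commands a nominal gradient waveform G(t); the amplifier
and coil play out a distorted version.  For non-Cartesian readouts the
k-space trajectory is the time integral of the played-out gradients, so
waveform errors accumulate into trajectory errors and, after gridding
reconstruction, into image artifacts — intensity distortion, blurring,
aliasing — and biased quantitative maps.  Two correction models are
implemented:

* **GIRF** — the gradient impulse response function, a per-axis LTI
  transfer function H(f) estimated by regularized frequency-domain least
  squares over a library of nominal/measured waveform pairs,

      H(f) = sum_n conj(I_n) O_n / (sum_n |I_n|^2 + lambda * max_f sum_n |I_n|^2),

  with all transforms zero-padded to at least twice the longest training
  waveform (linear, not circular, convolution).  lambda defaults to 1e-9
  (relative Tikhonov).  The GIRF is exact for linear, time-invariant
  distortions and is structurally blind to amplitude dependence and
  zero-crossing effects.

* **TCN** — a multistage temporal convolutional network mapping a causal
  window of the normalized nominal waveform (channel 1) plus a constant
  amplitude code (channel 2) to the normalized distorted sample at the
  window's last time point.  Each of the `n_res_blocks` residual blocks
  holds two weight-normalized causal convolutions (kernel `k`, dilation
  `2^i` in block i) with GELU activations and optional dropout, bypassed
  by a kernel-1 convolution; a final linear layer reads one scalar per
  time index.  Receptive field: `1 + 2(k-1)(2^Nres - 1)`; 931 samples for
  the reference configuration `Nres=5, k=16`.  The network output is added
  to the current nominal sample (an identity skip with a zero-initialized
  head), so the untrained network is the identity map and training learns
  the distortion *residual* — this materially accelerates convergence and
  is exact for an undistorted system.  An LSTM baseline (2 layers, hidden
  96) consumes the same inputs.

Because the causal convolutions are applied with left zero padding,
evaluating the network over a whole padded sequence is mathematically
identical to sliding a window one sample at a time, provided the window
covers the receptive field and is truncated (not padded) at the sequence
start; `sliding_window_predict` is the reference implementation the fast
path is verified against.

### Input normalization

Channel 1 is the nominal waveform divided by |A| (A = commanded signed
peak amplitude); channel 2 is |A| / A_sys with A_sys = 770 mT/m.  The
amplitude code is **unsigned**: gradient chains are odd-symmetric, so a
sign flip of the waveform carries all sign information in channel 1, and
rotated readout shots (whose per-axis peak may be negative) remain inside
the trained input distribution.  Targets are the measured samples divided
by the same |A|.

### Training

Mean absolute error minimized with Adam.  Rather than assembling explicit
stride-1 windows, training evaluates whole sequences convolutionally
(mathematically the same window set) and batches sequences of equal
length; `batch_size` therefore counts sequences.  The desk-scale defaults
used by the experiment driver are: 12 channels per convolution, dropout
0, learning rate 3e-3 with cosine decay to zero, batch of 1 sequence,
30 epochs, weight decay 9e-8, betas (0.9, 1-1e-6).  These were selected in
a small convergence study during development: per-window hyperparameters
(lr 8.4e-4, batch 32 windows, dropout 0.2) transfer poorly to
sequence-batch training, which takes far fewer, far less noisy optimizer
steps per epoch.  The `TCNConfig`/`TrainingConfig` dataclass defaults keep
the reference per-window values (64 channels, dropout 0.2, lr 8.4e-4) for
users who want them.  One seed controls initialization, shuffling and
dropout; two runs with the same seed agree to floating-point equality.

## The synthetic gradient system

No scanner is involved; "measured" waveforms come from a synthetic
nonlinear gradient chain whose stages reproduce, qualitatively, the
distortion families documented for real systems:

1. **Linear stage** — causal 3rd-order Butterworth low-pass (20 kHz),
   group delay (20 us), minus eddy-current terms
   `sum_j c_j * (dG/dt (*) exp(-t/tau_j)) dt` with
   (c, tau) = (0.003, 100 us), (0.001, 1 ms).
2. **Amplitude dependence** — gain `1 - 0.05 (1 - |A|/770)` and extra
   delay `16 us * (1 - |A|/770)`: weaker, later response at low drive.
3. **Crossover distortion** — dead zone `sign(x) max(|x| - 2 mT/m, 0)`,
   the push-pull amplifier's zero-crossing artifact.
4. **Slew-rate limiter** — recursive rate clamp at 5274 T/m/s
   (770 mT/m in 146 us).
5. Optional white measurement noise, sigma = 0.05 mT/m.

Stage order is fixed (linear -> amplitude -> crossover -> slew) and
matters, because the stages do not commute.  Fractional delays use a
causal first-order (linear-interpolation) interpolator: a band-limited
sinc interpolator would ring ahead of the delay and violate causality,
which is contractual (output at sample n never depends on later inputs);
the interpolator's mild high-frequency roll-off simply joins the modeled
band limitation.  With the nonlinear terms zeroed and the limiter off the
chain is exactly LTI (superposition to 1e-10), the regime in which GIRF
prediction must be — and is — near-exact.

These functional forms are synthetic stand-ins: parameter values were
fixed to magnitudes that visibly reproduce the documented phenomenology
(percent-level zero-crossing artifacts, amplitude-dependent delay of
order 10 us), not fitted to any hardware.  Relative to a well-maintained
scanner they are deliberately strong; see Limitations.

## Waveform library

18 shapes per axis: 11 training shapes (trapezoids, a bipolar trapezoid,
triangle trains, two slew-constrained chirps, three multisines, one spiral
readout waveform) at 15 amplitudes uniformly spanning 70-700 mT/m, and 7
validation shapes (spiral, two rosette waveforms, trapezoid, chirp,
multisine, triangle train) at 7 amplitudes over the same range — 214
nominal waveforms per axis.  Gradient raster: 4 us by default; the
experiment driver uses 8 us (content is below 15 kHz, so both rasters are
comfortably oversampled) to halve compute.

Two design constraints worth recording:

* Every shape carries a 1 ms zero tail: the "measurement window" extends
  past the gradient event so eddy-current decay is captured.  Without the
  tail, truncated decay biases the GIRF estimate and the LTI-limit
  validation error cannot reach 1e-4.
* Shapes are designed against a slew budget scaled so that rescaling to
  700 mT/m stays hardware-feasible — except the chirps (and the most
  demanding multisine copies), which intentionally engage the simulated
  rate limiter at high amplitude.  This is physical: a slew-feasible
  15 kHz chirp at 700 mT/m would need more than 7 ms just to reach its
  peak.  The clipped copies are realistic, strongly nonlinear training
  examples.

## Readouts, reconstruction, DTI

* **Spiral-in-out** (40 shots): Archimedean spiral traversed edge ->
  center -> opposite edge, uniform inter-shot rotation, trapezoidal
  prephaser pair moving k from the origin to the spiral-in start, echo
  (k = 0) at the readout midpoint.  The readout duration is chosen
  iteratively as the shortest meeting the amplitude and slew limits; at
  the default 130 mT/m cap it lands near the reference 5.3 ms.  A
  trapezoidal speed profile (cosine ramps over the first/last 8% of
  samples) lets the gradients start and end at zero.
* **Rosette** (40 shots, 5 petals):
  `k = k_max sin(w1 t) [cos(w2 t + phi_m), sin(w2 t + phi_m)]` with
  `w2/w1 = (n_petals-1)/n_petals`, `w1 T = n_petals pi`, uniform shot
  rotations, gradients computed analytically through the same time warp.
  Duration 6.712 ms (an integer number of rasters).
* **Acquisition** — exact discrete-Fourier summation over the phantom
  grid with optional per-sample off-resonance phase, times referenced to
  the echo.  Data are always simulated along the *measured* trajectory;
  each reconstruction variant then grids the same raw data with its own
  trajectory estimate — so every variant reconstructs identical raw data and differences are attributable to the trajectory estimate alone.
* **Reconstruction** — Pipe-Menon density compensation (kernel-convolution
  fixed point, 10 iterations by default; a warning reports
  non-convergence), Kaiser-Bessel gridding (width 6, oversampling 2,
  Beatty beta) with analytic deapodization, and optional time-segmented
  conjugate-phase off-resonance correction (8 segments, raised-cosine
  temporal interpolation).
* **Image error** — RMS of |img| - |ref| over max |ref| (the
  percent-signal-difference convention).  Magnitude comparison is
  essential: trajectory errors impose bulk phase ramps that dominate a
  complex difference without changing the artifact content.
* **DTI** — six dual-gradient directions + b=0 at b = 1000 s/mm2;
  mono-exponential tensor signals; two-pass weighted linear least squares
  (OLS, then weights = squared predicted signals) on the log-linearized
  model; MD/FA/RD/AD from eigenvalues clamped at zero (negative-eigenvalue
  fraction reported); Pearson correlations over voxels whose FA exceeds
  0.05 in both maps, all maps sharing the FA mask.  The full-pipeline DTI
  comparison runs on the rosette readout (see Limitations for why).

## Experiment scale

The end-to-end experiments run at desk scale on one CPU: 8 us raster,
3 axes, 30-epoch training per axis (~2 min/axis), 40-shot readouts,
N = 96 image grids at 30 mm FOV, noiseless acquisitions.  Reported
behavior at this scale: nominal waveforms err at NRMSE ~1.5e-1 on the
validation split, the GIRF improves this by roughly 8x (~1.9e-2), and the
TCN by another ~4-5x (~4e-3); normalized trajectory RMSE follows at
~0.10 / 0.04 / 0.015 for nominal / GIRF / TCN.

## Limitations

* The simulator is a phenomenological stand-in.  Passing tests show the
  *methods* behave correctly under the stated distortion families; they
  do not certify accuracy on any particular scanner, and real systems add
  effects that are out of scope here (temperature drift, cross-axis
  coupling, mechanical resonances, spatial field nonlinearity).
* The default distortion magnitudes are strong relative to a real
  scanner: the GIRF's residual trajectory error on the imaging readouts is
  ~4% of k_max, near the coherent-reconstruction limit (~2/N) at N = 96.
  Close to that limit, image NRMSE compresses: the GIRF and nominal
  reconstructions of the spiral differ by only ~8% in NRMSE (0.357 vs
  0.389) even though their trajectories differ 2.5-fold, and the
  comparison is sensitive to geometry — in particular the readout
  resolution must match the reconstruction grid (trajectories extending
  beyond the grid Nyquist corrupt the better variants disproportionately).
  The rosette separates the three methods more cleanly, which is why the
  DTI comparison runs on it.  TCN-based reconstructions order best for
  both readouts at both N = 96 and N = 64 (examples 06/07).
* The LSTM baseline is implemented and tested at interface parity but is
  not part of the default experiment (the TCN supersedes it).
* Diffusion-encoding gradients are applied analytically to the phantom
  signal; eddy currents from the diffusion lobes themselves are not
  modeled.
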