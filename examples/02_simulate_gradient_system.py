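"""Distort a nominal waveform through the synthetic gradient system.

The simulator chains a band-limited, delayed linear stage with exponential
eddy-current terms, amplitude-dependent gain/delay, zero-crossing dead-zone
distortion, slew-rate limiting, and measurement noise.  Low-amplitude
waveforms are attenuated and delayed more than high-amplitude ones — the
amplitude dependence a linear (GIRF) model cannot capture.
"""

import numpy as np

from gradpredict import (
    GradientSystemModel,
    make_triangle_train,
    scale_to_amplitudes,
    simulate_measurement,
    waveform_nrmse,
)

model = GradientSystemModel()
base = make_triangle_train(100.0, 4, 0.15e-3, dt=4e-6, axis="z")

print(f"{'amplitude':>10} {'NRMSE vs nominal':>18} {'peak out / peak in':>20}")
for w in scale_to_amplitudes(base, [70.0, 250.0, 500.0, 700.0]):
    meas = simulate_measurement(model, w, add_noise=False)
    nrmse = waveform_nrmse(w, meas)
    ratio = np.max(np.abs(meas.samples)) / np.max(np.abs(w.samples))
    print(f"{w.amp_scale:>8.0f}    {nrmse:>16.4f} {ratio:>20.4f}")
# NRMSE (normalized by the commanded peak) falls with amplitude and the
# output peak recovers toward the input peak: the simulated amplifier is
# weakest at low drive, exactly the phenomenology of push-pull stages.
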