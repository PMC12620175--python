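"""Estimate the gradient impulse response function (GIRF) and use it.

The GIRF is the LTI characterization of the gradient chain: a regularized
frequency-domain least-squares transfer function pooled over all training
waveform pairs.  On a purely linear system it predicts distorted waveforms
near-exactly; on the nonlinear system a residual remains.
"""

import numpy as np

from gradpredict import (
    GradientSystemModel,
    LibraryConfig,
    build_characterization_library,
    estimate_girf,
    predict_with_girf,
    simulate_library,
    waveform_nrmse,
)

lib = build_characterization_library(LibraryConfig(axes=("z",), dt=8e-6))

for label, model in [
    ("exactly LTI system ", GradientSystemModel().lti_limit()),
    ("nonlinear system   ", GradientSystemModel()),
]:
    paired = simulate_library(model, lib, add_noise=False)
    girf = estimate_girf(paired.subset("train", "z").pairs, regularization=1e-9)
    errs_nom, errs_girf = [], []
    for p in paired.subset("validation", "z"):
        errs_nom.append(waveform_nrmse(p.nominal, p.measured))
        errs_girf.append(
            waveform_nrmse(predict_with_girf(girf, p.nominal), p.measured)
        )
    print(
        f"{label}: validation NRMSE nominal={np.mean(errs_nom):.3e}  "
        f"GIRF={np.mean(errs_girf):.3e}"
    )
# On the LTI system the GIRF error collapses to ~1e-5 (estimation is exact
# up to regularization); on the nonlinear system it improves on the nominal
# waveform by roughly an order of magnitude but hits the nonlinearity floor.
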