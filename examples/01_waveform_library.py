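"""Build the gradient-system characterization library.

The library holds 18 waveform shapes — trapezoids, triangle trains,
slew-constrained chirps, multisines and single-shot readout waveforms —
split 11 train / 7 validation, with training shapes replicated at 15
amplitudes covering 70-700 mT/m and validation shapes at 7 amplitudes.
"""

import numpy as np

from gradpredict import LibraryConfig, build_characterization_library

lib = build_characterization_library(LibraryConfig(axes=("z",)))

train = lib.subset("train")
val = lib.subset("validation")
print(f"library: {len(lib)} waveforms on axis z")
print(f"  train:      {len(train):3d}  ({len(set(lib.labels('train')))} shapes x 15 amplitudes)")
print(f"  validation: {len(val):3d}  ({len(set(lib.labels('validation')))} shapes x 7 amplitudes)")
print()
print(f"{'shape':<20} {'samples':>8} {'peak mT/m':>10} {'max slew T/m/s':>15}")
seen = set()
for p in lib:
    w = p.nominal
    if w.label in seen:
        continue
    seen.add(w.label)
    print(
        f"{w.label:<20} {w.n:>8} {np.max(np.abs(w.samples)):>10.1f} "
        f"{w.numeric_slew().max():>15.0f}"
    )
# Peak amplitudes equal the first amplitude of each split's grid (70 mT/m);
# slew rates stay below the 770 mT/m / 146 us system limit (~5274 T/m/s)
# when shapes are rescaled across the amplitude grid.
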