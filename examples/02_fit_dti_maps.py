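"""Fit diffusion tensors and compare FA / ADC maps against the planted truth.

The log-linear tensor fit is exact on noiseless data; at SNR 30 the maps are
close to truth with a small noise-induced FA inflation (the Rician floor).
"""

import numpy as np

from wmischemia import compute_maps, default_spec
from wmischemia.phantom import AcquisitionScheme, simulate_subject

scheme = AcquisitionScheme()
spec = default_spec(n_subjects=2, seed=7, grid_shape=(16, 16, 4))
sub = simulate_subject(spec, scheme, 0)

fa_map, adc_map = compute_maps(sub.dwi, scheme, mask=sub.masks["brain"])

for name, code in [("normal WM", 1), ("hypoperfused WM", 3),
                   ("infarct core", 4)]:
    sel = sub.truth.label_map == code
    print(f"{name:16s} planted FA {sub.truth.true_fa[sel].mean():.3f}  "
          f"recovered {np.nanmean(fa_map.values[sel]):.3f}   "
          f"planted ADC {sub.truth.true_adc[sel].mean()*1e6:6.1f}e-6  "
          f"recovered {np.nanmean(adc_map.values[sel])*1e6:6.1f}e-6")
print("\nRecovered region means track the planted values; FA runs a few "
      "thousandths high because magnitude-MRI noise inflates anisotropy.")
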