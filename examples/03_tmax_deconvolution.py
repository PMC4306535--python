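"""Recover bolus delay (Tmax) by block-circulant SVD deconvolution.

A tissue curve is simulated as the gamma-variate arterial input convolved
with an exponential residue and delayed; deconvolution recovers the residue,
whose peak time is Tmax.  On the 1.45 s acquisition grid, grid-aligned
planted delays come back exactly; parabolic interpolation resolves
sub-sample delays to ~0.05 s.
"""

import numpy as np

from wmischemia.dsc import fit_tmax
from wmischemia.phantom import (GroundTruth, REGION_CODES, AcquisitionScheme,
                                default_spec, simulate_dsc)

scheme = AcquisitionScheme()
spec = default_spec(grid_shape=(2, 2, 1), dsc_noise_sd=0.0,
                    voxel_sd=dict(fa=0.0, md=0.0, tmax=0.0))
label = np.full((2, 2, 1), REGION_CODES["normal_wm"], dtype=np.int16)

print("planted Tmax -> recovered (grid)   recovered (interpolated)")
for planted in [0.0, 2.9, 5.4, 5.8, 7.3]:
    truth = GroundTruth(label, np.full((2, 2, 1), 0.36),
                        np.full((2, 2, 1), 0.75e-3),
                        np.full((2, 2, 1), planted),
                        region_values={}, principal_dirs={})
    sig, aif, aif_vox = simulate_dsc(spec, scheme, truth, seed=0)
    grid = fit_tmax(sig, aif, scheme).values[1, 1, 0]
    interp = fit_tmax(sig, aif, scheme, interpolate=True).values[1, 1, 0]
    print(f"   {planted:5.2f} s   ->  {grid:5.2f} s            {interp:5.3f} s")
print("\nGrid values are multiples of TR = 1.45 s; interpolation recovers "
      "delays that fall between samples (e.g. the 5.4 s threshold).")
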