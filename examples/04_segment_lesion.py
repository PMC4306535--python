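"""Threshold segmentation of infarcted vs hypoperfused vs normal WM.

Voxels with FA > 0.15 count as white matter; within it, ADC < 600e-6 mm^2/s
marks the infarct core and the remainder of the perfusion ROI is the
hypoperfused (penumbral) compartment.  The contralateral mirror ROI provides
the normal-WM reference.
"""

from wmischemia import default_spec, process_subject
from wmischemia.phantom import AcquisitionScheme, simulate_subject

spec = default_spec(n_subjects=2, seed=11, grid_shape=(16, 16, 4))
sub = simulate_subject(spec, AcquisitionScheme(), 0)

res = process_subject(sub)
masks = res["masks"]
vox_ml = 1.5 * 1.5 * 3.0 / 1000.0  # voxel volume in mL

print(f"WM voxels (FA>0.15):        {int(masks.wm.sum())}")
print(f"infarct core (ADC<600e-6):  {int(masks.infarct_core.sum())} voxels "
      f"= {masks.infarct_core.sum() * vox_ml:.2f} mL "
      f"(planted {int((sub.truth.label_map == 4).sum())})")
print(f"hypoperfused WM:            {int(masks.hypoperfused.sum())} voxels "
      f"(planted {int((sub.truth.label_map == 3).sum())})")
print(f"contralateral normal WM:    {int(masks.normal_contra.sum())} voxels")
print("\nper-region voxel means:")
print(res["table"].groupby("region")[["fa", "adc", "tmax"]].mean().round(4))
print("\nThe segmented compartments reproduce the planted lesion geometry; "
      "core ADC sits well below the threshold, hypoperfused Tmax is "
      "prolonged.")
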