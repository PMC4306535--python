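# wmischemia

Voxel-based quantitative analysis of white-matter (WM) ischemia in
hyperacute stroke from combined diffusion and perfusion MRI, together with a
digital phantom that makes every stage testable against known ground truth.

The package is aimed at neuroimaging researchers studying the
perfusion–diffusion mismatch: it reproduces, as an open and fully seeded
pipeline, the analysis in which fractional anisotropy (FA) is *elevated* in
hypoperfused-but-viable WM and *reduced* in the infarct core, and in which a
regression-tree split on the perfusion delay Tmax separates the two FA
regimes.

## What it computes

- **DTI maps** — per-voxel diffusion tensors by log-linear least squares on
  `ln S_i = ln S_0 − b gᵢᵀ D gᵢ`, then
  `FA = √(3/2)·‖λ − λ̄‖/‖λ‖` and `ADC = (λ₁+λ₂+λ₃)/3` from the (clamped,
  descending) eigenvalues.
- **Tmax maps** — DSC signal → concentration `C(t) = −ln(S/S₀)/TE`, then
  block-circulant SVD deconvolution against the arterial input function
  (zero-padded to 2N; singular values below 10 % of the maximum discarded);
  Tmax is the peak time of the recovered residue `k(t) = CBF·R(t−delay)`,
  on the TR grid or with parabolic sub-sample interpolation.
- **Segmentation** — WM = `FA > 0.15`; infarct core = WM with
  `ADC < 600×10⁻⁶ mm²/s`; hypoperfused WM = remaining WM inside the
  perfusion ROI; mirrored contralateral ROI = normal-WM reference.
- **Statistics** — person–region means; one-way repeated-measures ANOVA with
  Tukey-adjusted pairwise contrasts (studentized range on MS_error);
  Spearman correlations; and an exhaustive single-split search for the Tmax
  threshold minimizing within-group FA variance, with a selection-aware
  permutation p-value.
- **Phantom** — multi-subject DWI (20 directions, b = 1000 s/mm², Rician
  noise) and DSC series (60 timepoints, TR 1.45 s / TE 22 ms, gamma-variate
  AIF) with planted per-region FA/ADC/Tmax distributions, written as
  NIfTI + bval/bvec + TSV bundles.

## Worked example

`examples/05_cohort_statistics.py` simulates a 21-subject cohort whose
hypoperfused-WM FA steps from 0.390 to 0.423 at a planted 5.4 s Tmax
changepoint, runs the full pipeline and prints:

```
FA repeated-measures ANOVA: F(2,40) = 34.8, p = 1.75e-09
     region_a     region_b  mean_diff  p_tukey
normal_contra hypoperfused     0.0504   0.0000
normal_contra infarct_core    -0.0327   0.0063
 hypoperfused infarct_core    -0.0831   0.0000

Tmax split search (person level): threshold 5.43 s (planted changepoint 5.4 s)
  FA below/above: 0.396 / 0.427; difference 0.031; permutation p = 0.0015
```

The ANOVA confirms the three WM compartments differ in FA; the split search
recovers the planted changepoint to within a small fraction of the 1.45 s
acquisition grid, and the permutation test (which re-runs the whole search
on every shuffle, so it accounts for threshold selection) shows the FA step
is not a selection artifact.  The other examples cover phantom simulation,
tensor fitting, Tmax deconvolution and lesion segmentation individually.

A thin CLI mirrors the stages:

```sh
wmischemia phantom --out cohort/ --n-subjects 21 --seed 1
wmischemia run --cohort cohort/ --out report/
wmischemia fit-dti --dwi dwi.nii.gz --bval dwi.bval --bvec dwi.bvec --out maps/
wmischemia fit-dsc --dsc dsc.nii.gz --aif aif.txt --out maps/
```

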