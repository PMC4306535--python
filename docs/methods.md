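# Methods

This note documents the models, parameter choices and numerical decisions
behind `wmischemia`, and what the synthetic validation does and does not
demonstrate.

## Diffusion model and tensor estimation

Each voxel carries a single axially symmetric (prolate) diffusion tensor
`D = λ₂I + (λ₁−λ₂)vvᵀ` with a per-region principal direction `v`.  Given a
target (FA, MD) pair the eigenvalues follow in closed form: with
`d = λ₁−λ₂`, the FA definition reduces to
`d = FA·MD·√3 / √(1 − 2FA²/3)`, so `λ₁ = MD + 2d/3`, `λ₂ = λ₃ = MD − d/3`.
`λ₂ ≥ 0` holds for every FA in [0, 1), so the inversion is total on the
valid domain.  Axial symmetry is the simplest tensor family that spans all
(FA, MD) targets; real WM has orientation dispersion and crossing fibers
that this phantom does not emulate.

The estimator is ordinary log-linear least squares (design matrix in the
tensor's six unique components plus ln S₀), the canonical baseline that is
exact on noiseless data.  Weighted or nonlinear fits are deliberately out of
scope.  Eigenvalues are sorted descending and clamped at zero before FA/ADC
so FA stays in [0, 1].  Voxels with any nonpositive signal are excluded
(NaN) rather than floored — flooring would silently bias the log fit.

**Estimator bias.**  Magnitude-MRI (Rician) noise inflates estimated FA.
At the default baseline SNR of 30 with 20 directions the region-mean
inflation, measured on the phantom, is ≈ +0.007 at FA 0.36–0.40 and grows to
≈ +0.013 at FA 0.31 (the bias scales inversely with FA).  Recovered region
means therefore run a few thousandths above the planted values; the infarct
compartment is the worst case.  This is a property of the estimator under
noise, not of the implementation; the noiseless round trip is exact to 1e-6.

## DSC forward model and deconvolution

Tissue concentration follows `C(t) = CBF·(AIF ⊛ R)(t − delay)` with a
gamma-variate arterial input `(t−t₀)^α e^{−(t−t₀)/β}` (t₀ = 12 s, α = 2.5,
β = 1.2; onset leaves ≥ 8 pre-bolus baseline samples at TR 1.45 s) and an
exponential residue `R(t) = e^{−t/MTT}`.  The convolution is evaluated on a
10 ms grid and sampled at `t − delay` per voxel, so fractional delays are
true continuous shifts of the sampled curve.  The signal is
`S(t) = S₀e^{−TE·C(t)}` with additive Gaussian noise on the signal (noise
enters the scanner in signal space, not concentration space).  Amplitudes
are set so the tissue peak ΔR2* (≈16 s⁻¹) produces a ≈30 % signal drop at
TE 22 ms.  MTT defaults to 1.2 s — short relative to physiology — so the
residue is sharply peaked and Tmax, a pure delay measure, stays well defined
on the coarse 1.45 s grid; prolonged transit in real lesions smears the
residue peak and biases Tmax upward in ways this phantom does not model.

Deconvolution builds the AIF convolution matrix block-circulant at
zero-padded length 2N, which makes the inverse insensitive to bolus arrival
delay (cyclic shifts of the tissue curve cyclically shift the residue —
asserted directly in the tests).  Regularization is a fixed global
truncation of singular values below 10 % of the largest; an
oscillation-index adaptive threshold is not implemented.  The truncated SVD
of a circulant matrix equals Fourier-bin truncation; the FFT identity serves
as an independent oracle in the tests while the implementation keeps the
explicit SVD form.

**Delay calibration.**  Truncated-SVD deconvolution low-pass filters the
residue, so its peak sits a constant `τ*` after the true delay (`τ* ≈ 0.91 s`
for the default AIF/MTT/threshold).  The phantom measures `τ*` once by a
noiseless round trip through its own deconvolver and subtracts it when
planting delays, so that the *recovered* peak lands on the voxel's true
Tmax.  With this calibration, grid-aligned planted delays (0–8 TR) are
recovered exactly and arbitrary delays to ≈0.05 s with parabolic
interpolation; at a bolus-drop SNR of 30 the median absolute Tmax error is
≈0.08 s.  Tmax is reported on the TR grid by default; parabolic sub-sample
interpolation around the peak is a config flag (off by default) and is what
allows recovered thresholds that are not TR multiples, such as 5.4 s.

## Phantom population structure

Per-subject region values are drawn from truncated normal distributions
(FA in [0, 0.99], MD > 0, Tmax ≥ 0) around the configured mean ± SD, then a
small per-voxel truth jitter (FA 0.010, MD 15e-6 mm²/s, Tmax 0.3 s) is added
within regions.  Only between-subject SDs are published for the emulated
study; the within-region voxel variance is a free generator parameter kept
small so person-region means are dominated by the subject draw.

Default region parameters: FA 0.360 ± 0.020 (normal WM), 0.397 ± 0.019
(hypoperfused WM), 0.313 ± 0.037 (infarct core), 0.10 ± 0.02 (gray matter).
ADC defaults are field-typical values consistent with the published
constraints rather than transcriptions (the source tables are not available
as text): normal 780 ± 25 and hypoperfused 785 ± 30 (×10⁻⁶ mm²/s,
indistinguishable, as reported), infarct 480 ± 40 — clearly below the
600×10⁻⁶ core threshold.  The margin matters: the measured voxelwise ADC
estimator noise at SNR 30 is ≈37×10⁻⁶, and normal-WM means much below
≈750×10⁻⁶ would leak false-positive voxels into the ADC<600 core rule,
contradicting the premise that the threshold separates core from non-core
tissue.  Tmax defaults are 0.7 ± 0.4 s (normal and GM), 5.5 ± 1.5 s
(hypoperfused, spanning the 2–9 s penumbra-threshold literature) and
7.5 ± 1.5 s (core).

Geometry is deliberately schematic: a gray-matter slab, a rectangular
hypoperfused block containing a smaller infarct-core block in one
hemisphere, and the mirror-image contralateral ROI.  No partial volume,
distortion, motion or realistic anatomy.

The **step-FA mode** replaces the hypoperfused draw with a two-level
process: subject mean Tmax uniform on 2–9 s, FA 0.390 ± 0.014 below the
5.4 s changepoint and 0.423 ± 0.014 above it.  The **copula simulator**
draws (Tmax, FA) pairs from a Gaussian copula whose parameter is chosen so
the *expected sample* Spearman coefficient at the cohort size equals the
target, using the exact bivariate-normal relation
`E[r_s] = 6/(π(n+1))·((n−2)·asin(ρ/2) + asin(ρ))`; published coefficients
are sample statistics, and at n = 21 the naive large-n parameterization
would undershoot them by ≈0.02.

## Segmentation conventions

Thresholds are applied in physical units (FA dimensionless, ADC mm²/s,
Tmax s).  `FA > 0.15` is strict; ADC exactly at 600×10⁻⁶ is assigned to the
hypoperfused side so the two lesion classes partition the ROI (the published
rules use strict inequalities on both sides, leaving equality — a
measure-zero event — unassigned).  The hand-drawn perfusion ROI of the
original workflow is replaced by a user-supplied mask or the reproducible
surrogate `Tmax > contralateral mean + 2 SD` (falling back to mean + one TR
when the contralateral region has zero variance).  Whether the ADC core
rule should also be restricted to the perfusion ROI is ambiguous in the
source workflow; a `core_within_roi` flag exposes both behaviors (default
off, i.e. the core rule is global).  Coregistration is assumed done — all
maps must share one voxel grid; the phantom emits aligned maps by
construction.

Note that at SNR 30 the voxelwise FA estimate has SD ≈ 0.036, so a
gray-matter compartment planted at FA 0.10 is only ~70–80 % excluded by the
0.15 threshold; clean GM/WM separation by an FA cut alone requires either
higher SNR or a wider FA gap than cortical tissue provides.  The schematic
geometry keeps GM away from the analysis ROIs so this leak does not touch
the reported region statistics.

## Statistics

The unit of analysis is the person–region mean.  The "mixed
(repeated-measures)" model is implemented as classical one-way
within-subject ANOVA — with a single within factor and complete data the two
coincide, and F is invariant to per-subject additive shifts (tested).
Incomplete subjects are dropped with a warning.  Tukey pairwise contrasts
use the studentized range with MS_error and its (k−1)(n−1) df.  When
MS_error underflows to rounding noise (ss_error below 1e-12 of ss_total)
the p-values are reported at the floating-point floor with a flag rather
than as garbage ratios.

The split search enumerates midpoints between consecutive distinct sorted
Tmax values (TR-quantized grids collapse naturally), requires
`min_group_size` (default 2) on both sides, minimizes total within-group
SSE via prefix sums, and breaks ties toward the smaller threshold.  Its
primary p-value is a permutation test that re-runs the entire search on
each of 10,000 shuffles of FA against Tmax — accounting for threshold
selection — with an uncorrected Welch t-test reported as a secondary value.
The split defaults to person-level means: the small subgroup SDs reported
for the emulated analysis are consistent with person-level summaries, and a
voxel-level mode is provided because the source is ambiguous.  The
published significance values for the split were not used to calibrate
anything here; the test identity behind them is unknown.

## Validation scope

The recovery experiments (25 replicate cohorts of 21 subjects on a 32×32×8
grid, a size chosen to keep a full run in the minutes range on one CPU)
show that the pipeline recovers planted region FA means to well under 0.01
except for the infarct compartment (≈ +0.013, the estimator-bias worst case
above), the planted 5.4 s changepoint to ≈0.1 s on average (replicate SD
≈0.5 s, driven by the gap between flanking subjects), and the planted
subgroup FA difference to ≈0.001.  Passing these tests demonstrates
numerical correctness and statistical calibration of the chain on data that
satisfy the generative assumptions — aligned maps, single-tensor voxels,
sharp residue, Gaussian/Rician noise.  They do not validate performance
under motion, misregistration, partial volume, fiber crossings, leakage
effects or dispersed boluses, all of which are absent from the phantom.
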