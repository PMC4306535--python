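"""Default study conditions for the digital phantom and the analysis pipeline.

Region parameters encode the published tissue contrasts of hyperacute white-matter
(WM) ischemia: fractional anisotropy (FA) is mildly *elevated* in hypoperfused but
not-yet-infarcted WM (0.397 +/- 0.019) and *reduced* in the infarct core
(0.313 +/- 0.037) relative to contralateral normal WM (0.360 +/- 0.020).  The
infarct core additionally has restricted diffusion (ADC below the canonical
600e-6 mm^2/s cut-off) and the ischemic territory has a prolonged bolus delay
(Tmax).  ADC and Tmax region means are field-typical values consistent with
those constraints (normal and hypoperfused ADC statistically indistinguishable;
lesion Tmax spanning the 2-9 s range discussed in the penumbra literature).

The changepoint block drives the step-FA cohort used by the Tmax split-search
experiment: subject-level hypoperfused FA is 0.390 below a 5.4 s Tmax
changepoint and 0.423 above it (SD 0.014 for both), with subject mean Tmax
drawn uniformly on 2-9 s.

The association block stores rank correlations (Spearman) between person-level
region means, used by the copula cohort simulator.
"""

from __future__ import annotations

# Per-region planted parameters.  Units: FA dimensionless, ADC/MD mm^2/s, Tmax s.
# *_sd are between-subject SDs; voxel_* are within-region, per-voxel truth SDs
# (free parameters of the phantom, kept small so region means are dominated by
# the subject-level draw).
REGION_DEFAULTS = {
    "normal_wm": dict(
        fa_mean=0.360, fa_sd=0.020,
        md_mean=780e-6, md_sd=25e-6,
        tmax_mean=0.7, tmax_sd=0.4,
        s0=100.0,
    ),
    "gray_matter": dict(
        fa_mean=0.10, fa_sd=0.02,
        md_mean=850e-6, md_sd=40e-6,
        tmax_mean=0.7, tmax_sd=0.4,
        s0=100.0,
    ),
    "hypoperfused_wm": dict(
        fa_mean=0.397, fa_sd=0.019,
        md_mean=785e-6, md_sd=30e-6,
        tmax_mean=5.5, tmax_sd=1.5,
        s0=100.0,
    ),
    "infarct_core": dict(
        fa_mean=0.313, fa_sd=0.037,
        md_mean=480e-6, md_sd=40e-6,
        tmax_mean=7.5, tmax_sd=1.5,
        s0=100.0,
    ),
}

# Within-region per-voxel truth variation (same units as above).
VOXEL_SD = dict(fa=0.010, md=15e-6, tmax=0.30)

# DWI acquisition: 20 noncollinear directions at b=1000 s/mm^2 plus one b=0.
DWI_DEFAULTS = dict(n_directions=20, b_value=1000.0, n_b0=1)

# DSC acquisition: TR 1.45 s, TE 22 ms, 60 repetitions.
DSC_DEFAULTS = dict(tr=1.45, te=0.022, n_timepoints=60)

# DSC simulation constants.  The arterial input is a gamma-variate
# A*(t-t0)^alpha*exp(-(t-t0)/beta); onset 12 s leaves >= 8 pre-bolus baseline
# samples at TR 1.45 s.  Tissue mean transit time is short (1.2 s) so the
# residue function is sharply peaked and Tmax -- a pure delay measure -- is
# well defined on the coarse acquisition grid.  Amplitudes are chosen so the
# tissue peak DeltaR2* (~16 1/s) produces a ~30% signal drop at TE 22 ms.
AIF_DEFAULTS = dict(t0=12.0, alpha=2.5, beta=1.2, peak_conc=48.0)
DSC_SIM_DEFAULTS = dict(mtt=1.2, tissue_peak_conc=16.0, baseline_n=8)

# Default singular-value truncation of the block-circulant deconvolution,
# as a fraction of the largest singular value.
SVD_THRESHOLD_FRAC = 0.10

# Segmentation thresholds (the analysis' defining constants): voxels with
# FA > 0.15 count as WM; WM voxels with ADC < 600e-6 mm^2/s are infarct core.
THRESHOLD_DEFAULTS = dict(fa_wm=0.15, adc_core=600e-6, tmax_roi_k=2.0)

# Step-FA cohort for the Tmax split search.
CHANGEPOINT_DEFAULTS = dict(
    tmax_split=5.4,      # s; the planted changepoint
    fa_below=0.390,      # subject-level hypoperfused FA below the changepoint
    fa_above=0.423,      # ... and above it
    fa_sd=0.014,         # between-subject SD of both levels
    tmax_range=(2.0, 9.0),  # subject mean Tmax drawn uniformly on this range
)

# Person-level Spearman rank correlations between region-mean measures.
ASSOCIATION_DEFAULTS = {
    "normal_wm": {"fa_adc": -0.590, "adc_tmax": -0.021, "fa_tmax": 0.418},
    "hypoperfused_wm": {"fa_adc": -0.230, "adc_tmax": 0.319, "fa_tmax": 0.561},
    "infarct_core": {"fa_adc": 0.209, "adc_tmax": -0.681, "fa_tmax": -0.539},
}

# Statistics defaults.
STATS_DEFAULTS = dict(split_unit="person", min_group_size=2,
                      n_permutations=10_000, alpha=0.05)

PHANTOM_GRID = (32, 32, 8)
PHANTOM_VOXEL_SIZE = (1.5, 1.5, 3.0)  # mm
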