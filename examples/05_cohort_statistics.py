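"""Full cohort analysis: repeated-measures ANOVA, Tukey pairwise contrasts,
Spearman correlations and the Tmax split search.

Runs the end-to-end pipeline on a 21-subject phantom cohort whose
hypoperfused-WM FA steps from 0.390 to 0.423 at a planted 5.4 s Tmax
changepoint, then reports whether the split search finds it.
"""

from wmischemia import default_spec, io, run_pipeline
from wmischemia.defaults import CHANGEPOINT_DEFAULTS
from wmischemia.phantom import generate_cohort

spec = default_spec(n_subjects=21, seed=4,
                    changepoint=dict(CHANGEPOINT_DEFAULTS))
subjects = generate_cohort(spec)

cfg = io.default_config()
cfg["deconvolution"]["interpolate_tmax"] = True
cfg["statistics"]["n_permutations"] = 2000
report = run_pipeline(subjects, cfg)

print("region mean +/- SD (person-level):")
print(report["region_table"]["mean_fa"].round(4))

fa_anova = report["anova"]["mean_fa"]
print(f"\nFA repeated-measures ANOVA: F({fa_anova['df_num']},"
      f"{fa_anova['df_den']}) = {fa_anova['f']:.1f}, p = {fa_anova['p_value']:.2e}")
print(fa_anova["pairwise"].round(4).to_string(index=False))

split = report["split"]
print(f"\nTmax split search (person level): threshold {split.threshold:.2f} s"
      f" (planted changepoint {CHANGEPOINT_DEFAULTS['tmax_split']} s)")
print(f"  FA below/above: {split.mean_low:.3f} / {split.mean_high:.3f}; "
      f"difference {split.mean_difference:.3f}; permutation p = "
      f"{split.p_value:.4f}")
print("\nA small permutation p here means the FA step across the recovered "
      "Tmax threshold is larger than chance under reshuffling.")
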