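"""Cohort statistics: person-region summaries, one-way repeated-measures
ANOVA with Tukey-adjusted pairwise comparisons, Spearman correlations, and a
single-split regression-tree search on Tmax.

The unit of analysis is the person-region mean (voxel values are first
averaged per subject and region).  The split search finds the Tmax threshold
minimizing the total within-group sum of squared FA deviations over all
midpoints between consecutive distinct Tmax values; its primary p-value is a
selection-aware permutation test that re-runs the full search on each
permutation, with an uncorrected Welch t-test reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import defaults as dflt

__all__ = ["AnovaResult", "SplitResult", "summarize", "rm_anova",
           "spearman", "best_split", "analyze_cohort"]

log = logging.getLogger(__name__)

REGION_ORDER = ["normal_contra", "hypoperfused", "infarct_core"]


# ---------------------------------------------------------------------------
# summaries

def summarize(voxel_table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-region voxel means of FA / ADC / Tmax.

    Subjects with no voxels in a region are simply absent from the output
    (never reported as zero).
    """
    required = {"subject", "region", "fa", "adc", "tmax"}
    missing = required - set(voxel_table.columns)
    if missing:
        raise ValueError(f"voxel table lacks columns {sorted(missing)}")
    g = voxel_table.groupby(["subject", "region"], sort=True)
    out = g.agg(mean_fa=("fa", "mean"), mean_adc=("adc", "mean"),
                mean_tmax=("tmax", "mean"), n_voxels=("fa", "size"))
    return out.reset_index()


# ---------------------------------------------------------------------------
# repeated-measures ANOVA + Tukey

@dataclass
class AnovaResult:
    f: float
    df_num: int
    df_den: int
    p_value: float
    pairwise: pd.DataFrame          # region_a, region_b, mean_diff, p_tukey
    zero_error: bool = False        # MS_error underflow flag


def rm_anova(summaries: pd.DataFrame, value: str = "mean_fa",
             regions: list[str] | None = None) -> AnovaResult:
    """One-way within-subject ANOVA across regions, plus Tukey HSD.

    F = MS_region / MS_error with df (k-1) and (k-1)(n-1), after removing the
    per-subject effect.  Pairwise comparisons use the studentized range with
    MS_error and the error df.  Subjects missing any region are dropped
    (complete-case) with a warning.
    """
    regions = regions or [r for r in REGION_ORDER
                          if r in set(summaries["region"])]
    wide = (summaries.pivot(index="subject", columns="region", values=value)
            .reindex(columns=regions))
    complete = wide.dropna()
    if len(complete) < len(wide):
        log.warning("rm_anova: dropped %d incomplete subjects",
                    len(wide) - len(complete))
    n, k = complete.shape
    if n < 3:
        raise ValueError("repeated-measures ANOVA needs at least 3 complete subjects")
    y = complete.to_numpy(dtype=float)

    grand = y.mean()
    ss_region = n * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_subject = k * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_error = ss_total - ss_region - ss_subject
    df_num = k - 1
    df_den = (k - 1) * (n - 1)
    ms_region = ss_region / df_num
    ms_error = max(ss_error / df_den, 0.0)

    # treat error variance as zero when it is pure float cancellation noise
    zero_error = ss_error <= 1e-12 * max(ss_total, np.finfo(float).tiny)
    if zero_error:
        f = np.inf if ms_region > 0 else 0.0
        p = np.finfo(float).tiny if ms_region > 0 else 1.0
    else:
        f = ms_region / ms_error
        p = float(sps.f.sf(f, df_num, df_den))

    rows = []
    se = np.sqrt(ms_error / n) if not zero_error else 0.0
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(y[:, j].mean() - y[:, i].mean())
            if zero_error:
                p_t = np.finfo(float).tiny if diff != 0 else 1.0
            else:
                q = abs(diff) / se
                p_t = float(sps.studentized_range.sf(q, k, df_den))
            rows.append(dict(region_a=regions[i], region_b=regions[j],
                             mean_diff=diff, p_tukey=p_t))
    return AnovaResult(f=float(f), df_num=df_num, df_den=df_den, p_value=p,
                       pairwise=pd.DataFrame(rows), zero_error=zero_error)


# ---------------------------------------------------------------------------
# Spearman

def spearman(x, y):
    """Spearman rank correlation with average-rank ties and t-approximation
    p-value.  Returns (r_s, p); (nan, nan) when either variable has zero rank
    variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman needs two equal-length samples of n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("spearman requires finite values")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        log.warning("spearman: zero rank variance, correlation undefined")
        return float("nan"), float("nan")
    r, p = sps.spearmanr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# single-split regression tree on Tmax

@dataclass
class SplitResult:
    threshold: float        # s; midpoint between two observed Tmax values
    n_low: int
    n_high: int
    mean_low: float         # FA mean of the Tmax < threshold group
    mean_high: float
    mean_difference: float  # mean_high - mean_low
    p_value: float          # selection-aware permutation p
    p_welch: float          # uncorrected Welch t-test, secondary
    criterion: float        # total within-group SSE at the chosen split


def _split_profile(y_sorted: np.ndarray, valid: np.ndarray):
    """Within-group SSE for every split position (split after index i-1).

    ``y_sorted`` may be (n,) or (B, n) for B permutations; returns the SSE
    profile masked to ``valid`` positions (+inf elsewhere).
    """
    y = np.atleast_2d(y_sorted)
    n = y.shape[-1]
    csum = np.cumsum(y, axis=-1)
    csq = np.cumsum(y * y, axis=-1)
    i = np.arange(1, n)                      # low-group sizes
    sum_lo = csum[:, :-1]
    sq_lo = csq[:, :-1]
    sse_lo = sq_lo - sum_lo ** 2 / i
    sum_hi = csum[:, -1:] - sum_lo
    sq_hi = csq[:, -1:] - sq_lo
    sse_hi = sq_hi - sum_hi ** 2 / (n - i)
    prof = sse_lo + sse_hi
    return np.where(valid[None, :], prof, np.inf)


def best_split(tmax, fa, min_group_size: int = 2,
               n_permutations: int = 10_000, seed: int = 0) -> SplitResult:
    """Exhaustive search for the Tmax threshold that best splits FA.

    Candidates are midpoints between consecutive distinct sorted Tmax values;
    the winner minimizes total within-group SSE of FA, ties broken toward the
    smaller threshold.  The permutation p-value shuffles FA against Tmax and
    re-runs the whole search each time, so it accounts for threshold
    selection; the Welch t-test on the selected groups is reported as an
    uncorrected secondary value.
    """
    t = np.asarray(tmax, dtype=float)
    y = np.asarray(fa, dtype=float)
    if t.size != y.size:
        raise ValueError("tmax and fa lengths differ")
    n = t.size
    if min_group_size < 1:
        raise ValueError("min_group_size must be >= 1")
    if n < 2 * min_group_size:
        raise ValueError("too few observations for the requested group sizes")
    if np.unique(t).size < 2:
        raise ValueError("need at least 2 distinct Tmax values to split")

    order = np.argsort(t, kind="stable")
    ts, ys = t[order], y[order]
    i = np.arange(1, n)
    valid = (ts[1:] > ts[:-1]) & (i >= min_group_size) & (n - i >= min_group_size)
    if not np.any(valid):
        raise ValueError("no admissible split satisfies min_group_size")

    prof = _split_profile(ys, valid)[0]
    best = int(np.argmin(prof))              # argmin takes the first == smallest threshold
    crit = float(prof[best])
    thr = float(0.5 * (ts[best] + ts[best + 1]))
    lo, hi = ys[: best + 1], ys[best + 1:]

    rng = np.random.default_rng(seed)
    if n_permutations > 0:
        perm = rng.permuted(np.broadcast_to(ys, (n_permutations, n)), axis=1)
        null_crit = _split_profile(perm, valid).min(axis=-1)
        p_perm = float((np.sum(null_crit <= crit) + 1) / (n_permutations + 1))
    else:
        p_perm = float("nan")
    t_res = sps.ttest_ind(hi, lo, equal_var=False)
    return SplitResult(
        threshold=thr, n_low=lo.size, n_high=hi.size,
        mean_low=float(lo.mean()), mean_high=float(hi.mean()),
        mean_difference=float(hi.mean() - lo.mean()),
        p_value=p_perm, p_welch=float(t_res.pvalue), criterion=crit)


# ---------------------------------------------------------------------------
# full report

def analyze_cohort(summaries: pd.DataFrame,
                   voxel_tables: pd.DataFrame | None = None,
                   config: dict | None = None, seed: int = 0) -> dict:
    """Full statistical report for one cohort.

    Sections: region mean +/- SD per measure; RM-ANOVA with Tukey pairwise
    differences; Spearman correlations per region between the three measures;
    and the Tmax split search on hypoperfused WM (FA subgroup means above /
    below the threshold, in hypoperfused and infarcted WM).  ``split_unit``
    selects person-level means (default) or pooled voxels for the split.
    """
    cfg = dict(dflt.STATS_DEFAULTS)
    cfg.update(config or {})
    if summaries["subject"].nunique() < 3:
        raise ValueError("cohort analysis needs at least 3 subjects")

    region_table = (summaries.groupby("region")[["mean_fa", "mean_adc", "mean_tmax"]]
                    .agg(["mean", "std", "count"]))

    anova = {}
    for value in ("mean_adc", "mean_fa", "mean_tmax"):
        res = rm_anova(summaries, value=value)
        anova[value] = dict(f=res.f, df_num=res.df_num, df_den=res.df_den,
                            p_value=res.p_value, zero_error=res.zero_error,
                            pairwise=res.pairwise)

    correlations = []
    for region, sub in summaries.groupby("region"):
        for a, b in (("mean_fa", "mean_adc"), ("mean_adc", "mean_tmax"),
                     ("mean_fa", "mean_tmax")):
            if len(sub) >= 3:
                r, p = spearman(sub[a].to_numpy(), sub[b].to_numpy())
                correlations.append(dict(region=region, pair=f"{a[5:]}-{b[5:]}",
                                         r_s=r, p=p))
    correlations = pd.DataFrame(correlations)

    unit = cfg["split_unit"]
    if unit == "person":
        hyp = summaries[summaries["region"] == "hypoperfused"]
        t_arr = hyp["mean_tmax"].to_numpy()
        f_arr = hyp["mean_fa"].to_numpy()
    elif unit == "voxel":
        if voxel_tables is None:
            raise ValueError("split_unit='voxel' requires voxel tables")
        hyp = voxel_tables[voxel_tables["region"] == "hypoperfused"]
        t_arr = hyp["tmax"].to_numpy()
        f_arr = hyp["fa"].to_numpy()
    else:
        raise ValueError("split_unit must be 'person' or 'voxel'")
    split = best_split(t_arr, f_arr, min_group_size=cfg["min_group_size"],
                       n_permutations=cfg["n_permutations"], seed=seed)

    # FA subgroup means at the found threshold, in both lesion compartments
    subgroups = {}
    for region in ("hypoperfused", "infarct_core"):
        sub = summaries[summaries["region"] == region]
        lo = sub[sub["mean_tmax"] < split.threshold]["mean_fa"]
        hi = sub[sub["mean_tmax"] >= split.threshold]["mean_fa"]
        subgroups[region] = dict(
            below=dict(n=int(lo.size), mean_fa=float(lo.mean()) if lo.size else float("nan")),
            above=dict(n=int(hi.size), mean_fa=float(hi.mean()) if hi.size else float("nan")))

    return dict(region_table=region_table, anova=anova,
                correlations=correlations, split=split,
                split_unit=unit, subgroups=subgroups)
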