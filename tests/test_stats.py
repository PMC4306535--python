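import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from wmischemia.stats import (analyze_cohort, best_split, rm_anova, spearman,
                              summarize)


def _summaries(values: dict[str, list[float]], value_col="mean_fa"):
    rows = []
    regions = ["normal_contra", "hypoperfused", "infarct_core"]
    for subject, vals in values.items():
        for region, v in zip(regions, vals):
            rows.append({"subject": subject, "region": region, value_col: v,
                         "mean_adc": 0.0, "mean_tmax": 0.0})
    return pd.DataFrame(rows)


class TestSummarize:
    def test_voxel_means(self):
        table = pd.DataFrame({
            "subject": ["a"] * 3, "region": ["hypoperfused"] * 2 + ["infarct_core"],
            "fa": [0.3, 0.4, 0.2], "adc": [7e-4, 8e-4, 5e-4],
            "tmax": [6.0, 7.0, 8.0]})
        out = summarize(table)
        hyp = out[out["region"] == "hypoperfused"].iloc[0]
        assert hyp["mean_fa"] == pytest.approx(0.35)
        assert hyp["n_voxels"] == 2
        core = out[out["region"] == "infarct_core"].iloc[0]
        assert core["mean_fa"] == pytest.approx(0.2)  # single voxel

    def test_empty_region_absent_not_zero(self):
        table = pd.DataFrame({"subject": ["a"], "region": ["hypoperfused"],
                              "fa": [0.3], "adc": [7e-4], "tmax": [6.0]})
        out = summarize(table)
        assert set(out["region"]) == {"hypoperfused"}

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            summarize(pd.DataFrame({"subject": [], "fa": []}))


class TestRmAnova:
    # hand-computed oracle (exact rational arithmetic):
    #   subjects s1..s4, regions (normal, hypoperfused, infarct):
    #   s1 (.30,.40,.25) s2 (.32,.41,.28) s3 (.29,.38,.24) s4 (.33,.43,.27)
    #   SS_region = 0.0434, SS_subject = 0.00303333.., SS_error = 0.00026666..
    #   F = (0.0434/2) / (0.000266../6) = 1953/4 = 488.25 on df (2, 6)
    HAND = {"s1": [0.30, 0.40, 0.25], "s2": [0.32, 0.41, 0.28],
            "s3": [0.29, 0.38, 0.24], "s4": [0.33, 0.43, 0.27]}

    def test_hand_computed_four_subject_table(self):
        res = rm_anova(_summaries(self.HAND))
        assert res.f == pytest.approx(488.25, abs=1e-10)
        assert (res.df_num, res.df_den) == (2, 6)
        assert res.p_value == pytest.approx(2.2774878774925036e-07, rel=1e-6)
        pw = res.pairwise.set_index(["region_a", "region_b"])
        assert pw.loc[("normal_contra", "hypoperfused"), "mean_diff"] == \
            pytest.approx(0.095, abs=1e-12)
        assert pw.loc[("normal_contra", "hypoperfused"), "p_tukey"] == \
            pytest.approx(2.407024e-06, rel=1e-5)
        assert pw.loc[("hypoperfused", "infarct_core"), "mean_diff"] == \
            pytest.approx(-0.145, abs=1e-12)

    def test_identical_region_means_give_f_zero_p_one(self):
        vals = {f"s{i}": [0.3 + 0.01 * i] * 3 for i in range(4)}
        res = rm_anova(_summaries(vals))
        assert res.f == 0.0
        assert res.p_value == 1.0

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        rows = []
        for s in range(7):
            base = rng.normal(0, 0.02)
            for r, mu in [("normal_contra", 0.36), ("hypoperfused", 0.40),
                          ("infarct_core", 0.31)]:
                rows.append(dict(subject=f"s{s}", region=r,
                                 mean_fa=mu + base + rng.normal(0, 0.01)))
        df = pd.DataFrame(rows)
        res = rm_anova(df, "mean_fa")
        aov = pg.rm_anova(data=df, dv="mean_fa", within="region",
                          subject="subject")
        assert res.f == pytest.approx(float(aov["F"][0]), rel=1e-10)

    def test_invariant_to_per_subject_constant(self, rng):
        vals = {f"s{i}": list(rng.normal(0.35, 0.03, 3)) for i in range(6)}
        shifted = {s: [v + i * 0.5 for v in vs]
                   for i, (s, vs) in enumerate(vals.items())}
        f1 = rm_anova(_summaries(vals)).f
        f2 = rm_anova(_summaries(shifted)).f
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="3"):
            rm_anova(_summaries({"s1": [1, 2, 3], "s2": [1, 2, 3]}))

    def test_zero_error_flagged(self):
        vals = {f"s{i}": [0.30, 0.40, 0.25] for i in range(4)}
        res = rm_anova(_summaries(vals))
        assert res.zero_error
        assert res.p_value <= np.finfo(float).tiny


class TestSpearman:
    def test_monotone_is_one(self):
        assert spearman([1, 2, 3], [3, 5, 9])[0] == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        assert spearman([1, 2, 3], [9, 5, 3])[0] == pytest.approx(-1.0)

    @pytest.mark.parametrize("x,y", [
        ([1, 2, 2, 3, 5], [2, 2, 4, 4, 4]),
        ([1, 1, 1, 2, 3, 3], [5, 4, 4, 4, 2, 1]),
    ])
    def test_ties_equal_rank_then_pearson_oracle(self, x, y):
        rx = sps.rankdata(x)  # average-rank tie handling
        ry = sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y)[0] == pytest.approx(expected, abs=1e-12)

    def test_zero_rank_variance_is_nan(self):
        r, p = spearman([1.0, 1.0, 1.0], [1, 2, 3])
        assert np.isnan(r) and np.isnan(p)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, np.nan], [1, 2, 3])


def _exhaustive_split_oracle(t, y, min_group_size):
    """O(n^2) brute force over all midpoints between distinct Tmax values."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    uniq = np.unique(t)
    best = None
    for a, b in zip(uniq[:-1], uniq[1:]):
        thr = 0.5 * (a + b)
        lo, hi = y[t < thr], y[t >= thr]
        if len(lo) < min_group_size or len(hi) < min_group_size:
            continue
        sse = (np.sum((lo - lo.mean()) ** 2) + np.sum((hi - hi.mean()) ** 2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, thr)
    return best


class TestBestSplit:
    def test_five_point_worked_example(self):
        res = best_split([1, 2, 3, 10, 11], [0.30, 0.31, 0.29, 0.40, 0.41],
                         min_group_size=2, n_permutations=0)
        assert res.threshold == pytest.approx(6.5)
        assert res.mean_low == pytest.approx(0.30)
        assert res.mean_high == pytest.approx(0.405)
        assert res.mean_difference == pytest.approx(0.105)
        assert (res.n_low, res.n_high) == (3, 2)

    def test_constant_fa_tie_breaks_to_smallest_threshold(self):
        res = best_split([1, 2, 3, 4, 5, 6], [0.4] * 6, min_group_size=2,
                         n_permutations=500, seed=3)
        assert res.threshold == pytest.approx(2.5)  # smallest admissible midpoint
        assert res.p_value > 0.9

    def test_planted_step_recovered(self, rng):
        tmax = rng.uniform(2, 9, 21)
        fa = np.where(tmax >= 5.4, 0.423, 0.390) + rng.normal(0, 0.005, 21)
        res = best_split(tmax, fa, min_group_size=2, n_permutations=0)
        below = tmax[tmax < 5.4].max()
        above = tmax[tmax >= 5.4].min()
        assert below < res.threshold < above

    @given(st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_equals_exhaustive_oracle(self, data):
        n = data.draw(st.integers(4, 200))
        seed = data.draw(st.integers(0, 10_000))
        r = np.random.default_rng(seed)
        # heavy ties mimic TR-quantized Tmax grids
        t = r.choice(np.arange(0, 12) * 1.45, size=n)
        if np.unique(t).size < 2:
            t[0], t[1] = 0.0, 1.45
        y = r.normal(0.4, 0.03, n)
        oracle = _exhaustive_split_oracle(t, y, 2)
        if oracle is None:  # no admissible split under the group-size floor
            with pytest.raises(ValueError):
                best_split(t, y, min_group_size=2, n_permutations=0)
            return
        res = best_split(t, y, min_group_size=2, n_permutations=0)
        sse, thr = oracle
        assert res.criterion == pytest.approx(sse, abs=1e-9)
        assert res.threshold == pytest.approx(thr, abs=1e-9)

    def test_matches_sklearn_tree_threshold(self, rng):
        sklearn = pytest.importorskip("sklearn.tree")
        t = rng.uniform(0, 10, 50)
        y = rng.normal(0.4, 0.05, 50) + 0.05 * (t > 6)
        res = best_split(t, y, min_group_size=2, n_permutations=0)
        tree = sklearn.DecisionTreeRegressor(
            max_depth=1, min_samples_leaf=2).fit(t[:, None], y)
        # sklearn casts features to float32 internally
        assert res.threshold == pytest.approx(float(tree.tree_.threshold[0]),
                                              abs=1e-5)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            best_split([2.9, 2.9, 2.9, 2.9], [1, 2, 3, 4])
        with pytest.raises(ValueError, match="few"):
            best_split([1, 2, 3], [1, 2, 3], min_group_size=2)

    def test_permutation_p_detects_real_step(self, rng):
        t = rng.uniform(2, 9, 21)
        y = np.where(t >= 5.4, 0.423, 0.390) + rng.normal(0, 0.01, 21)
        res = best_split(t, y, n_permutations=2000, seed=1)
        assert res.p_value < 0.01
        assert res.p_welch < 0.01


class TestAnalyzeCohort:
    @pytest.fixture()
    def cohort(self, rng):
        rows, vox = [], []
        for s in range(8):
            tm = rng.uniform(2, 9)
            for region, fa, adc, tmax in [
                    ("normal_contra", 0.36, 780e-6, 0.7),
                    ("hypoperfused", 0.40, 785e-6, tm),
                    ("infarct_core", 0.31, 480e-6, tm + 2)]:
                rows.append(dict(subject=f"s{s}", region=region,
                                 mean_fa=fa + rng.normal(0, 0.01),
                                 mean_adc=adc, mean_tmax=tmax, n_voxels=50))
                for v in range(5):
                    vox.append(dict(subject=f"s{s}", region=region, voxel=v,
                                    fa=fa + rng.normal(0, 0.02), adc=adc,
                                    tmax=tmax + rng.normal(0, 0.2)))
        return pd.DataFrame(rows), pd.DataFrame(vox)

    def test_report_contains_all_sections(self, cohort):
        summaries, vox = cohort
        rep = analyze_cohort(summaries, vox,
                             config={"n_permutations": 200}, seed=0)
        assert {"region_table", "anova", "correlations", "split",
                "subgroups"} <= set(rep)
        assert set(rep["anova"]) == {"mean_adc", "mean_fa", "mean_tmax"}
        assert {"hypoperfused", "infarct_core"} == set(rep["subgroups"])

    def test_voxel_and_person_units_both_supported(self, cohort):
        summaries, vox = cohort
        rp = analyze_cohort(summaries, vox, config={"n_permutations": 0},
                            seed=0)
        rv = analyze_cohort(summaries, vox,
                            config={"n_permutations": 0, "split_unit": "voxel"},
                            seed=0)
        assert rp["split_unit"] == "person"
        assert rv["split_unit"] == "voxel"
        assert rv["split"].n_low + rv["split"].n_high == len(
            vox[vox["region"] == "hypoperfused"])

    def test_too_few_subjects_rejected(self, cohort):
        summaries, vox = cohort
        small = summaries[summaries["subject"].isin(["s0", "s1"])]
        with pytest.raises(ValueError):
            analyze_cohort(small, vox)
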