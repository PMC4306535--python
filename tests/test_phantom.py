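import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wmischemia import defaults as dflt
from wmischemia import dti
from wmischemia.phantom import (GroundTruth, PhantomSpec, RegionParams,
                                build_geometry, default_spec, draw_subject_truth,
                                generate_cohort, region_truth_table,
                                simulate_dsc, simulate_dwi, simulate_subject,
                                solve_eigenvalues, REGION_CODES)


class TestSolveEigenvalues:
    def test_isotropic(self):
        l1, l2, l3 = solve_eigenvalues(0.0, 0.7e-3)
        assert l1 == l2 == l3 == pytest.approx(0.7e-3, abs=1e-15)

    @pytest.mark.parametrize("fa,md", [(0.397, 0.75e-3), (0.313, 0.8e-3),
                                       (0.360, 0.72e-3), (0.9, 1e-3)])
    def test_round_trip_through_fa_definition(self, fa, md):
        lam = solve_eigenvalues(fa, md)
        assert np.mean(lam) == pytest.approx(md, abs=1e-12)
        assert dti.fa_from_eigenvalues(*lam) == pytest.approx(fa, abs=1e-10)
        assert lam[0] >= lam[1] == lam[2] >= 0

    def test_limit_fa_to_one_collapses_radial_eigenvalue(self):
        _, l2, _ = solve_eigenvalues(0.999999, 1e-3)
        assert l2 == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("fa,md", [(-0.1, 1e-3), (1.0, 1e-3), (0.5, 0.0)])
    def test_invalid_inputs_rejected(self, fa, md):
        with pytest.raises(ValueError):
            solve_eigenvalues(fa, md)

    @given(fa=st.floats(0.0, 0.98), md=st.floats(1e-5, 3e-3))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_inversion_property(self, fa, md):
        lam = solve_eigenvalues(fa, md)
        assert np.mean(lam) == pytest.approx(md, rel=1e-10)
        assert dti.fa_from_eigenvalues(*lam) == pytest.approx(fa, abs=1e-9)


class TestGeometry:
    def test_all_regions_present_and_rois_consistent(self):
        label, masks = build_geometry((32, 32, 8))
        for code in REGION_CODES.values():
            assert np.any(label == code)
        lesion = masks["perfusion_roi"]
        contra = masks["contra_roi"]
        assert not np.any(lesion & contra)
        # the contralateral ROI is the mirror image and sits in normal WM
        assert np.array_equal(contra, lesion[::-1, :, :])
        assert np.all(label[contra] == REGION_CODES["normal_wm"])


class TestSimulateDwi:
    def test_isotropic_noiseless_signals_equal(self, scheme):
        spec = default_spec(grid_shape=(4, 4, 2), snr_dwi=np.inf,
                            voxel_sd=dict(fa=0.0, md=0.0, tmax=0.0))
        label = np.full((4, 4, 2), REGION_CODES["normal_wm"], dtype=np.int16)
        md = 0.7e-3
        truth = GroundTruth(label, np.zeros((4, 4, 2)),
                            np.full((4, 4, 2), md), np.zeros((4, 4, 2)),
                            region_values={}, principal_dirs={
                                n: np.array([1.0, 0, 0]) for n in REGION_CODES})
        dwi, (dirs, bvals) = simulate_dwi(spec, scheme, truth, seed=0)
        s0 = spec.regions["normal_wm"].s0
        expected = s0 * np.exp(-scheme.b_value * md)
        dwivals = dwi[..., bvals > 0]
        assert np.allclose(dwivals, expected, rtol=1e-12)
        assert np.allclose(dwi[..., bvals == 0], s0)

    def test_noiseless_round_trip_recovers_tensor(self, noiseless_spec, scheme):
        sub = simulate_subject(noiseless_spec, scheme, 0)
        tensor, s0 = dti.fit_tensor(sub.dwi, scheme, sub.masks["brain"])
        lab = sub.truth.label_map
        for name, code in REGION_CODES.items():
            sel = (lab == code) & sub.masks["brain"]
            fa = sub.truth.true_fa[sel][0]
            md = sub.truth.true_adc[sel][0]
            l1, l2, _ = solve_eigenvalues(fa, md)
            v = sub.truth.principal_dirs[name]
            expected = l2 * np.eye(3) + (l1 - l2) * np.outer(v, v)
            assert np.allclose(tensor[sel], expected, atol=1e-8)

    def test_deterministic_given_seed(self, small_spec, scheme):
        truth = draw_subject_truth(small_spec, np.random.default_rng(3))
        a, _ = simulate_dwi(small_spec, scheme, truth, seed=42)
        b, _ = simulate_dwi(small_spec, scheme, truth, seed=42)
        assert np.array_equal(a, b)

    def test_grid_mismatch_rejected(self, small_spec, scheme):
        truth = draw_subject_truth(small_spec, np.random.default_rng(3))
        bad = PhantomSpec(grid_shape=(8, 8, 4))
        with pytest.raises(ValueError, match="grid"):
            simulate_dwi(bad, scheme, truth, seed=0)

    def test_rician_fa_bias_positive_in_isotropic_region(self, scheme):
        # known Rician floor: noise inflates FA where the truth is isotropic
        shape = (12, 12, 4)
        spec = default_spec(grid_shape=shape, snr_dwi=30.0,
                            voxel_sd=dict(fa=0.0, md=0.0, tmax=0.0))
        label = np.full(shape, REGION_CODES["normal_wm"], dtype=np.int16)
        truth = GroundTruth(label, np.zeros(shape), np.full(shape, 0.75e-3),
                            np.zeros(shape), region_values={},
                            principal_dirs={n: np.array([0, 0, 1.0])
                                            for n in REGION_CODES})
        dwi, _ = simulate_dwi(spec, scheme, truth, seed=9)
        fa_map, _ = dti.compute_maps(dwi, scheme)
        assert np.nanmean(fa_map.values) > 0


class TestSimulateDsc:
    def test_no_bolus_gives_zero_concentration(self, scheme):
        from wmischemia.dsc import signal_to_concentration
        sig = np.full(scheme.dsc_n_timepoints, 80.0)
        conc, flagged = signal_to_concentration(sig, scheme.dsc_te, 8)
        assert np.allclose(conc, 0.0)
        assert not flagged

    def test_baseline_window_is_prebolus(self, noiseless_spec, scheme):
        sub = simulate_subject(noiseless_spec, scheme, 0)
        sig = sub.dsc[sub.masks["brain"]]
        # at least 8 pre-bolus samples: baseline flat at s0
        assert np.allclose(sig[:, :8], sig[:, :1], rtol=1e-10)

    def test_deterministic_given_seed(self, small_spec, scheme):
        truth = draw_subject_truth(small_spec, np.random.default_rng(3))
        a, aif_a, _ = simulate_dsc(small_spec, scheme, truth, seed=7)
        b, aif_b, _ = simulate_dsc(small_spec, scheme, truth, seed=7)
        assert np.array_equal(a, b)
        assert np.array_equal(aif_a, aif_b)

    def test_delay_beyond_window_rejected(self, scheme):
        shape = (4, 4, 2)
        spec = default_spec(grid_shape=shape)
        label = np.full(shape, REGION_CODES["normal_wm"], dtype=np.int16)
        truth = GroundTruth(label, np.full(shape, 0.3),
                            np.full(shape, 0.75e-3), np.full(shape, 500.0),
                            region_values={}, principal_dirs={})
        with pytest.raises(ValueError, match="window"):
            simulate_dsc(spec, scheme, truth, seed=0)


class TestGenerateCohort:
    def test_zero_sd_subjects_identical(self, scheme):
        regions = {}
        for name, p in dflt.REGION_DEFAULTS.items():
            q = dict(p)
            q.update(fa_sd=0.0, md_sd=0.0, tmax_sd=0.0)
            regions[name] = RegionParams(label=name, **q)
        spec = default_spec(grid_shape=(16, 16, 4), n_subjects=2, seed=3,
                            regions=regions, snr_dwi=np.inf, dsc_noise_sd=0.0,
                            voxel_sd=dict(fa=0.0, md=0.0, tmax=0.0))
        subs = generate_cohort(spec, scheme)
        assert np.array_equal(subs[0].truth.true_fa, subs[1].truth.true_fa)
        assert np.array_equal(subs[0].truth.true_adc, subs[1].truth.true_adc)
        assert np.array_equal(subs[0].truth.true_tmax, subs[1].truth.true_tmax)

    def test_same_seed_reproduces_truth_exactly(self, small_spec, scheme):
        a = generate_cohort(small_spec, scheme)
        b = generate_cohort(small_spec, scheme)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.truth.true_fa, sb.truth.true_fa)
            assert np.array_equal(sa.dwi, sb.dwi)
            assert np.array_equal(sa.dsc, sb.dsc)

    def test_cohort_truth_means_match_configured_targets(self, scheme):
        spec = default_spec(n_subjects=21, seed=2, grid_shape=(16, 16, 4))
        subs = generate_cohort(spec, scheme)
        table = region_truth_table(subs)
        for region, p in dflt.REGION_DEFAULTS.items():
            fa = table[table["region"] == region]["fa"]
            se = p["fa_sd"] / np.sqrt(len(fa))
            assert abs(fa.mean() - p["fa_mean"]) < 3 * max(se, 1e-9)


class TestCorrelatedPairs:
    def test_rank_correlation_calibration(self):
        from wmischemia.phantom import simulate_correlated_pairs
        from wmischemia.stats import spearman
        rng = np.random.default_rng(7)
        rs = [spearman(*simulate_correlated_pairs(0.561, 21, rng))[0]
              for _ in range(400)]
        assert np.mean(rs) == pytest.approx(0.561, abs=0.03)

    def test_negative_target(self):
        from wmischemia.phantom import simulate_correlated_pairs
        from wmischemia.stats import spearman
        rng = np.random.default_rng(8)
        rs = [spearman(*simulate_correlated_pairs(-0.539, 21, rng))[0]
              for _ in range(200)]
        assert np.mean(rs) == pytest.approx(-0.539, abs=0.05)
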