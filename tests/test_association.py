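"""Pairing statistics, permutation counting, and reproducibility logic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from picalink import (
    DecompositionConfig,
    SyntheticConfig,
    bonferroni_threshold,
    empirical_p,
    generate_linked_dataset,
    generate_null_dataset,
    group_difference_loadings,
    kfold_reproducibility,
    overlap_ratio,
    pair_correlation_matrix,
    partial_correlation,
    permutation_test,
    run_parallel_ica,
    subgroup_rerun,
    within_group_partial_correlation,
)


class TestPairMatrix:
    def test_nine_by_seven_gives_63_tests(self):
        rng = np.random.default_rng(0)
        r, p = pair_correlation_matrix(rng.random((50, 9)), rng.random((50, 7)))
        assert r.size == 63 and p.size == 63

    def test_identical_columns_give_r_one(self):
        rng = np.random.default_rng(1)
        A1 = rng.random((20, 2))
        A2 = np.column_stack([A1[:, 0], rng.random(20)])
        r, _ = pair_correlation_matrix(A1, A2)
        assert r[0, 0] == pytest.approx(1.0)

    def test_matches_hand_computation_on_six_subjects(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = np.array([2.0, 1.0, 4.0, 3.0, 7.0, 5.0])
        r, p = pair_correlation_matrix(a[:, None], b[:, None])
        # hand Pearson: r = cov / (sa*sb)
        rm = ((a - a.mean()) * (b - b.mean())).sum() / np.sqrt(
            ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
        assert r[0, 0] == pytest.approx(rm, abs=1e-12)
        t = rm * np.sqrt(4 / (1 - rm**2))
        assert p[0, 0] == pytest.approx(2 * stats.t.sf(abs(t), 4), abs=1e-12)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            pair_correlation_matrix(np.random.random((3, 2)),
                                    np.random.random((3, 2)))


class TestPartialCorrelation:
    def test_covariate_itself_partials_to_zero(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(50)
        a = rng.standard_normal(50)
        r, p = partial_correlation(a, z, z)
        assert abs(r) < 1e-10

    def test_no_covariates_reduces_to_pearson(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal((2, 30))
        r, p = partial_correlation(a, b, np.empty((30, 0)))
        rr, pp = stats.pearsonr(a, b)
        assert r == pytest.approx(rr, abs=1e-12)
        assert p == pytest.approx(pp, rel=1e-6)

    def test_matches_recursive_formula_oracle(self):
        # 8-point example, one covariate: r_ab.c via the recursion
        a = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 7.0, 6.0, 8.0])
        b = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0, 8.0, 7.0])
        c = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0, 6.0])
        r_ab = stats.pearsonr(a, b)[0]
        r_ac = stats.pearsonr(a, c)[0]
        r_bc = stats.pearsonr(b, c)[0]
        oracle = (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))
        r, _ = partial_correlation(a, b, c)
        assert r == pytest.approx(oracle, abs=1e-10)

    def test_invariant_to_affine_covariate_rescaling(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal((2, 40))
        Z = rng.standard_normal((40, 3))
        r1, p1 = partial_correlation(a, b, Z)
        r2, p2 = partial_correlation(a, b, Z * 100.0 + 7.0)
        assert r1 == pytest.approx(r2, abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-10)

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal(20)
        with pytest.raises(ValueError):
            partial_correlation(rng.standard_normal(20),
                                rng.standard_normal(20),
                                np.column_stack([z, 2 * z]))


class TestBonferroni:
    def test_63_tests_threshold(self):
        assert bonferroni_threshold(0.05, 63) == pytest.approx(7.94e-4,
                                                               abs=1e-6)

    def test_trivial_cases_and_exactness(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.01, 10) == pytest.approx(0.001)
        for m in (1, 7, 63, 1000):
            assert bonferroni_threshold(0.05, m) * m == pytest.approx(0.05)


class TestGroupDifference:
    def test_identical_groups_give_p_near_one(self):
        x = np.tile([1.0, 2.0, 3.0], 10)
        dx = np.repeat([1, 0], 15)
        t, p, means = group_difference_loadings(np.concatenate([x[:15], x[:15]]),
                                                dx)
        assert p > 0.99
        assert means["case_mean"] == pytest.approx(means["control_mean"])

    def test_matches_textbook_computation(self):
        x1 = np.array([5.0, 6.0, 7.0, 6.5, 5.5])
        x0 = np.array([4.0, 4.5, 5.0, 4.2, 4.8])
        t, p, _ = group_difference_loadings(
            np.concatenate([x1, x0]), np.repeat([1, 0], 5))
        sp = np.sqrt(((x1.var(ddof=1) * 4) + (x0.var(ddof=1) * 4)) / 8)
        t_hand = (x1.mean() - x0.mean()) / (sp * np.sqrt(2 / 5))
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), 8), abs=1e-12)

    def test_power_of_unit_shift_matches_noncentral_t_oracle(self):
        """Simulated detection rate of a d=1 shift at n=160 agrees with the
        analytic noncentral-t power for p < 1e-6."""
        n1, n0, alpha = 73, 87, 1e-6
        df = n1 + n0 - 2
        ncp = 1.0 / np.sqrt(1 / n1 + 1 / n0)
        tcrit = stats.t.isf(alpha / 2, df)
        power = stats.nct.sf(tcrit, df, ncp)
        rng = np.random.default_rng(0)
        hits = 0
        reps = 300
        for _ in range(reps):
            x = rng.standard_normal(n1 + n0)
            x[:n1] += 1.0
            _, p, _ = group_difference_loadings(x, np.repeat([1, 0], (n1, n0)))
            hits += p < alpha
        assert abs(hits / reps - power) < 0.08


class TestWithinGroup:
    def test_full_cohort_mask_equals_partial_correlation(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal((2, 40))
        Z = rng.standard_normal((40, 2))
        assert within_group_partial_correlation(a, b, Z, np.ones(40, bool)) \
            == partial_correlation(a, b, Z)

    def test_tiny_group_rejected(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal((2, 40))
        Z = rng.standard_normal((40, 3))
        mask = np.zeros(40, bool)
        mask[:5] = True
        with pytest.raises(ValueError):
            within_group_partial_correlation(a, b, Z, mask)

    def test_group_mean_driven_link_vanishes_within_groups(self):
        """When the cross-modality association is carried purely by the
        group-mean difference, pooled r is large but within-group r ~ 0."""
        rng = np.random.default_rng(2)
        dx = np.repeat([1, 0], 80)
        a = -1.5 * dx + rng.standard_normal(160) * 0.5
        b = 1.5 * dx + rng.standard_normal(160) * 0.5
        pooled = stats.pearsonr(a, b)[0]
        Z = np.empty((160, 0))
        r_case, _ = within_group_partial_correlation(a, b, Z, dx == 1)
        r_ctrl, _ = within_group_partial_correlation(a, b, Z, dx == 0)
        assert pooled < -0.5
        assert abs(r_case) < 0.25 and abs(r_ctrl) < 0.25


class TestEmpiricalP:
    def test_one_exceedance_in_5000_gives_2e_minus_4(self):
        null = np.linspace(0.05, 0.30, 4999).tolist() + [0.40]
        assert empirical_p(0.37, null) == pytest.approx(2.00e-4)

    def test_observed_below_null_minimum_gives_one(self):
        assert empirical_p(0.01, np.linspace(0.1, 0.3, 100)) == 1.0

    def test_adding_small_null_value_never_changes_numerator(self):
        rng = np.random.default_rng(0)
        null = rng.random(200)
        obs = 0.7
        base = empirical_p(obs, null) * 200
        grown = empirical_p(obs, np.append(null, 0.0)) * 201
        assert base == grown


class TestPermutationTest:
    def test_counting_formula_and_profile_recorded(self):
        cfg = SyntheticConfig(seed=0, n_voxels=200, n_snps=120,
                              n_components_fa=3, n_components_snp=3)
        fa, geno, _, _ = generate_null_dataset(cfg)
        dcfg = DecompositionConfig(n_comp_fa=3, n_comp_snp=3, seed=0,
                                   max_iterations=24)
        res = permutation_test(fa.values, geno.calls, dcfg, n_perm=20, seed=1,
                               perm_config=dcfg.reduced(24))
        assert len(res.null_values) == 20
        assert res.empirical_p == (res.null_values >= res.observed).mean()
        assert res.profile.startswith("reduced")

    def test_invalid_n_perm_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(np.random.random((10, 5)),
                             np.random.random((10, 5)),
                             DecompositionConfig(n_comp_fa=2, n_comp_snp=2),
                             n_perm=0)


class TestOverlapRatio:
    def test_examples(self):
        assert overlap_ratio({1, 2, 3}, {1, 2, 3}) == 1.0
        assert overlap_ratio({4, 5}, {1, 2, 3}) == 0.0
        sub = set(range(1, 201)) | set(range(400, 526))
        full = set(range(1, 327))
        assert overlap_ratio(sub, full) == pytest.approx(200 / 326)

    def test_empty_full_set_rejected(self):
        with pytest.raises(ValueError):
            overlap_ratio({1}, set())


class TestKFold:
    def test_leave_one_out_on_tiny_data_runs(self):
        rng = np.random.default_rng(0)
        n = 12
        X1 = rng.laplace(size=(n, 60))
        X2 = rng.laplace(size=(n, 40))
        cfg = DecompositionConfig(n_comp_fa=2, n_comp_snp=2, seed=0,
                                  max_iterations=16)
        folds = kfold_reproducibility(X1, X2, cfg, k=n, seed=0)
        assert len(folds) == n
        assert all(len(f.kept_subjects) == n - 1 for f in folds)

    def test_strong_signal_folds_recover_the_pair(self, small_linked):
        fa, geno, cov, truth = small_linked
        cfg = DecompositionConfig(n_comp_fa=5, n_comp_snp=4, seed=1,
                                  max_iterations=160)
        folds = kfold_reproducibility(fa.values, geno.calls, cfg,
                                      diagnosis=cov["diagnosis"].to_numpy(),
                                      k=5, seed=2)
        rs = np.array([f.pair_correlation for f in folds])
        full = run_parallel_ica(fa.values, geno.calls, cfg).top_pair()[2]
        assert np.median(np.abs(np.abs(rs) - abs(full))) <= 0.15
        assert np.median([f.overlap_ratio for f in folds]) > 0.4

    def test_fold_sizes_use_90_percent(self):
        rng = np.random.default_rng(1)
        X1 = rng.laplace(size=(40, 80))
        X2 = rng.laplace(size=(40, 50))
        cfg = DecompositionConfig(n_comp_fa=2, n_comp_snp=2, seed=0,
                                  max_iterations=12)
        folds = kfold_reproducibility(X1, X2, cfg, k=10, seed=0)
        assert len(folds) == 10
        for f in folds:
            assert len(f.kept_subjects) == 36
        # held-out blocks are disjoint and cover everyone
        held = [set(range(40)) - {int(s) for s in f.kept_subjects}
                for f in folds]
        assert sorted(x for h in held for x in h) == list(range(40))


class TestSubgroupRerun:
    def test_full_mask_equals_full_run(self, small_linked):
        fa, geno, cov, _ = small_linked
        cfg = DecompositionConfig(n_comp_fa=5, n_comp_snp=4, seed=3,
                                  max_iterations=60)
        res_full = run_parallel_ica(fa.values, geno.calls, cfg)
        res_sub, pair = subgroup_rerun(fa.values, geno.calls, cov,
                                       np.ones(len(cov), bool), cfg)
        np.testing.assert_array_equal(res_full.A1, res_sub.A1)
        assert abs(pair.raw_r) <= 1

    def test_majority_subgroup_preserves_link(self, small_linked):
        fa, geno, cov, truth = small_linked
        mask = (cov["ethnicity"] == "caucasian").to_numpy()
        cfg = DecompositionConfig(n_comp_fa=5, n_comp_snp=4, seed=3)
        res, pair = subgroup_rerun(fa.values, geno.calls, cov, mask, cfg)
        # matched against truth restricted to the subgroup
        li, lj = truth.linked_pair
        c_fa = abs(np.corrcoef(truth.true_S1[li],
                               res.S1[pair.fa_component])[0, 1])
        assert c_fa > 0.8
        assert abs(pair.raw_r) > 0.25

    def test_single_diagnosis_subgroup_rejected(self, small_linked):
        fa, geno, cov, _ = small_linked
        mask = (cov["diagnosis"] == 1).to_numpy()
        with pytest.raises(ValueError):
            subgroup_rerun(fa.values, geno.calls, cov, mask,
                           DecompositionConfig(n_comp_fa=3, n_comp_snp=3))
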