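"""Paired non-parametric statistics layer: Wilcoxon, max-statistic
permutation test, Spearman, two-stage FDR, Dunn, outliers, EYBSO."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

import megpipe as mp
from megpipe.synthetic import OnsetRecord


class TestWilcoxon:
    def test_all_positive_n6_matches_enumeration(self):
        carrier = np.array([1.0, 2, 3, 4, 5, 6])
        surrogate = np.zeros(6)
        exact = mp.wilcoxon_paired(
            mp.PairedSample(carrier, surrogate), exact=True
        )
        assert exact.p == pytest.approx(2 / 64)  # only +/- all-signs tie it
        approx = mp.wilcoxon_paired(mp.PairedSample(carrier, surrogate))
        assert approx.z == pytest.approx(-2.2014, abs=1e-3)
        assert approx.p == pytest.approx(0.0277, abs=1e-3)

    def test_symmetric_differences_give_zero_z(self):
        d = np.array([1.0, -1.0, 2.0, -2.0])
        r = mp.wilcoxon_paired(mp.PairedSample(d, np.zeros(4)))
        assert r.z == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_single_nonzero_difference_matches_exact_n1(self):
        d = np.array([0.0, 0.0, 0.0, 3.0])
        r = mp.wilcoxon_paired(mp.PairedSample(d, np.zeros(4)), exact=True)
        assert r.n_effective == 1
        assert r.p == pytest.approx(1.0)  # 2/2 under the n=1 sign flip

    def test_all_zero_differences_flagged_undefined(self):
        r = mp.wilcoxon_paired(mp.PairedSample(np.ones(4), np.ones(4)))
        assert r.undefined and np.isnan(r.p)

    def test_approx_p_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            c, s = rng.standard_normal(12), rng.standard_normal(12)
            ours = mp.wilcoxon_paired(mp.PairedSample(c, s))
            ref = sps.wilcoxon(c, s, correction=False, method="approx")
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_type_one_error_calibrated_under_symmetric_null(self):
        # rejection rate at alpha=0.05 within binomial error, n=11 pairs
        rng = np.random.default_rng(42)
        n_sim = 1000
        rejections = 0
        for _ in range(n_sim):
            d = rng.standard_normal(11)
            if mp.wilcoxon_paired(mp.PairedSample(d, np.zeros(11))).p < 0.05:
                rejections += 1
        rate = rejections / n_sim
        margin = 3 * np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) < margin + 0.005


class TestRegionalPermutation:
    def test_corrected_never_below_uncorrected(self):
        rng = np.random.default_rng(1)
        res = mp.regional_permutation_test(
            rng.standard_normal((15, 8)), rng.standard_normal((15, 8)),
            n_perm=300, seed=2,
        )
        assert np.all(res.p_corrected >= res.p_uncorrected)
        assert np.all(res.p_uncorrected >= 1 / 301)

    def test_monte_carlo_matches_exhaustive_sign_flips_n4(self):
        rng = np.random.default_rng(3)
        carriers = rng.standard_normal((5, 4))
        surrogates = rng.standard_normal((5, 4))
        d = carriers - surrogates
        n = 4

        def paired_t(dd):
            return dd.mean(axis=1) / (dd.std(axis=1, ddof=1) / np.sqrt(n))

        t_obs = paired_t(d)
        # exhaustive 2^4 = 16 sign-flip null
        exact_counts = np.zeros(5)
        for signs in itertools.product((-1.0, 1.0), repeat=n):
            t_p = paired_t(d * np.array(signs))
            exact_counts += np.abs(t_p) >= np.abs(t_obs) - 1e-12
        exact_p = exact_counts / 16
        res = mp.regional_permutation_test(carriers, surrogates,
                                           n_perm=4000, seed=4)
        # Monte-Carlo within binomial error of the exhaustive distribution
        se = np.sqrt(exact_p * (1 - exact_p) / 4000) + 1e-3
        assert np.all(np.abs(res.p_uncorrected - exact_p) < 4 * se + 1 / 4001)

    def test_large_injected_shift_is_corrected_significant(self):
        hits_shifted, hits_others = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            carriers = rng.standard_normal((10, 11))
            surrogates = rng.standard_normal((10, 11))
            carriers[4] += 4.0  # one region with a large paired shift
            res = mp.regional_permutation_test(carriers, surrogates,
                                               n_perm=500, seed=seed)
            hits_shifted += res.p_corrected[4] < 0.05
            hits_others += np.sum(np.delete(res.p_corrected, 4) < 0.05)
        assert hits_shifted >= 19
        assert hits_others <= 10  # stray significances stay rare

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            mp.regional_permutation_test(np.ones((3, 1)), np.zeros((3, 1)))


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2, 3, 5, 8])
        assert mp.spearman(x, x**3)[0] == pytest.approx(1.0)
        assert mp.spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_tied_example_matches_rank_formula(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        y = np.array([5.0, 5.0, 7.0, 8.0, 9.0])
        rho, _ = mp.spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        manual = np.corrcoef(rx, ry)[0, 1]  # Pearson on mid-ranks
        assert rho == pytest.approx(manual, abs=1e-12)

    def test_constant_input_undefined(self):
        assert np.isnan(mp.spearman(np.ones(5), np.arange(5.0))[0])


class TestFdrBky:
    def test_extremes(self):
        reject, _ = mp.fdr_bky(np.ones(6))
        assert not reject.any()
        reject, _ = mp.fdr_bky(np.full(6, 1e-12))
        assert reject.all()

    def test_hand_computed_example(self):
        # stage 1 at q' = 0.05/1.05 rejects 3 -> m0 = 2;
        # stage 2 thresholds i*0.05/2 reject exactly the first three
        p = np.array([0.001, 0.01, 0.02, 0.2, 0.8])
        reject, adj = mp.fdr_bky(p, q=0.05)
        assert reject.tolist() == [True, True, True, False, False]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_two_stage(self, seed):
        p = np.random.default_rng(seed).uniform(1e-6, 1.0, 40)
        ours, _ = mp.fdr_bky(p, q=0.05)
        ref = multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
        assert np.array_equal(ours, ref)

    def test_flags_monotone_in_p(self):
        p = np.array([0.001, 0.002, 0.04, 0.2, 0.5, 0.9])
        reject, _ = mp.fdr_bky(p)
        # once a larger p is rejected, all smaller ones are too
        assert np.all(np.diff(reject.astype(int)) <= 0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            mp.fdr_bky(np.array([0.0, 0.5]))

    def test_empty_input(self):
        reject, adj = mp.fdr_bky(np.array([]))
        assert reject.size == 0 and adj.size == 0


class TestIqrOutliers:
    def test_symmetric_data_no_flags(self):
        assert mp.iqr_outliers(np.array([-2.0, -1, 0, 1, 2])) == []

    def test_hand_computed_fence(self):
        # values (1..4, 100): Q1=2, Q3=4, fences (-1, 7) -> only 100 flagged
        flagged = mp.iqr_outliers(np.array([1.0, 2, 3, 4, 100]),
                                  ids=["a", "b", "c", "d", "e"])
        assert flagged == ["e"]

    def test_translation_invariance(self):
        x = np.array([1.0, 2, 3, 4, 100])
        assert mp.iqr_outliers(x) == mp.iqr_outliers(x + 57.3)

    def test_needs_four_values(self):
        with pytest.raises(ValueError):
            mp.iqr_outliers(np.array([1.0, 2, 3]))


class TestKruskalDunn:
    def test_identical_groups(self):
        g = [np.arange(8.0), np.arange(8.0), np.arange(8.0)]
        res = mp.kruskal_dunn(g)
        assert res.h_statistic == pytest.approx(0.0, abs=1e-10)
        assert all(p_adj > 0.9 for *_, p_adj in res.pairwise)

    def test_separated_groups_detected(self):
        g = [np.arange(10.0), np.arange(10.0) + 100]
        res = mp.kruskal_dunn(g)
        assert res.p < 0.001
        assert res.pairwise[0][4] < 0.01
        assert res.df == 1

    def test_h_matches_rank_formula_with_ties(self):
        groups = [np.array([1.0, 2, 2]), np.array([2.0, 3, 3]),
                  np.array([1.0, 3, 4])]
        res = mp.kruskal_dunn(groups)
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        n = pooled.size
        start, h = 0, 0.0
        for g in groups:
            r = ranks[start:start + g.size]
            h += r.sum() ** 2 / g.size
            start += g.size
        h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
        _, counts = np.unique(pooled, return_counts=True)
        h /= 1 - np.sum(counts**3 - counts) / (n**3 - n)
        assert res.h_statistic == pytest.approx(h, abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mp.kruskal_dunn([np.arange(3.0), np.array([])])


class TestEybso:
    def test_sign_convention(self):
        rec = OnsetRecord(parental_onset_age=50.0, family_mean_onset_age=47.0,
                          mutation_mean_onset_age=49.0)
        out = mp.eybso(49.0, rec)
        assert out["parent"] == pytest.approx(1.0)  # onset still ahead
        assert out["mutation"] == pytest.approx(0.0)

    def test_passed_onset_is_negative(self):
        out = mp.eybso(55.0, OnsetRecord(family_mean_onset_age=47.0))
        assert out["family"] == pytest.approx(-8.0)

    def test_sibling_fallback_for_missing_parental(self):
        out = mp.eybso(40.0, OnsetRecord(sibling_onset_age=45.0))
        assert out["parent"] == pytest.approx(5.0)

    def test_missing_record_yields_none(self):
        out = mp.eybso(40.0, OnsetRecord())
        assert out == {"parent": None, "family": None, "mutation": None}

    def test_invalid_age_rejected(self):
        with pytest.raises(ValueError):
            mp.eybso(-1.0, OnsetRecord(parental_onset_age=50.0))
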