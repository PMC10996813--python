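import math
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from alclomics import stats_core as sc
from _oracles import (dip_lp_oracle, fisher_enumeration_oracle,
                      wilcoxon_enumeration_oracle)


class TestDip:
    def test_equally_spaced_four_points_attain_lower_bound(self):
        assert sc.dip_statistic([1.0, 2.0, 3.0, 4.0]) == pytest.approx(0.125,
                                                                      abs=1e-8)

    def test_two_equal_point_masses_approach_quarter(self):
        d = sc.dip_statistic([0.0] * 20 + [1.0] * 20)
        assert 0.2 <= d <= 0.25 + 1e-9

    @pytest.mark.parametrize("rep", range(12))
    def test_matches_lp_oracle_small_samples(self, rep):
        rng = np.random.default_rng(100 + rep)
        n = int(rng.integers(4, 11))
        if rep % 3 == 0:
            x = rng.normal(size=n)
        elif rep % 3 == 1:
            x = np.concatenate([rng.normal(-2, 0.3, n // 2),
                                rng.normal(2, 0.3, n - n // 2)])
        else:
            x = rng.integers(0, 4, n).astype(float)
        assert sc.dip_statistic(x) == pytest.approx(dip_lp_oracle(x), abs=1e-6)

    @given(st.lists(st.floats(-50, 50), min_size=5, max_size=25, unique=True),
           st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance_and_bounds(self, xs, a, b):
        x = np.array(xs)
        d = sc.dip_statistic(x)
        assert sc.dip_statistic(a * x + b) == pytest.approx(d, abs=1e-7)
        n = x.size
        assert 1.0 / (2 * n) - 1e-9 <= d <= 0.25 + 1e-9

    def test_batch_matches_single(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 12))
        batch = sc.dip_statistics(X)
        single = [sc.dip_statistic(row, tol=1e-8) for row in X]
        assert np.allclose(batch, single, atol=1e-12)

    def test_input_validation(self):
        with pytest.raises(sc.InsufficientDataError):
            sc.dip_statistic([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            sc.dip_statistic([1.0, 2.0, np.nan, 4.0])


class TestSpearman:
    def test_monotone_invariance(self):
        x = np.arange(1.0, 9.0)
        assert sc.spearman_rho(x, x ** 3) == pytest.approx(1.0)
        assert sc.spearman_rho(x, -(x ** 3)) == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 5, 30).astype(float)
        y = rng.integers(0, 5, 30).astype(float) + 0.3 * x
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert sc.spearman_rho(x, y) == pytest.approx(oracle, abs=1e-12)
        assert sc.spearman_rho(x, y) == pytest.approx(sps.spearmanr(x, y)[0],
                                                      abs=1e-12)

    def test_constant_vector_is_an_error_not_zero(self):
        with pytest.raises(sc.UndefinedStatisticError):
            sc.spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestWilcoxon:
    def test_identical_samples_exact_p_one(self):
        r = sc.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3], mode="exact")
        assert r.p_value == pytest.approx(1.0)

    def test_tiny_separated_groups(self):
        r = sc.wilcoxon_rank_sum([1, 2], [3, 4], mode="exact")
        assert r.p_value == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=4)
        y = rng.normal(0.5, 1.0, size=4)
        r = sc.wilcoxon_rank_sum(x, y, mode="exact")
        assert r.p_value == pytest.approx(wilcoxon_enumeration_oracle(x, y),
                                          abs=1e-12)

    def test_exact_matches_scipy_on_untied_data(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=6), rng.normal(1.0, 1.0, size=5)
        r = sc.wilcoxon_rank_sum(x, y, mode="exact")
        assert r.p_value == pytest.approx(
            sps.mannwhitneyu(x, y, method="exact").pvalue, abs=1e-10)

    def test_normal_approx_close_to_exact(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=4), rng.normal(size=4)
        pe = sc.wilcoxon_rank_sum(x, y, mode="exact").p_value
        pn = sc.wilcoxon_rank_sum(x, y, mode="normal_approx").p_value
        assert abs(pe - pn) < 0.05

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            sc.wilcoxon_rank_sum([], [1.0])


class TestFisher:
    def test_symmetric_table(self):
        assert sc.fisher_exact_2x2(1, 1, 1, 1).p_value == pytest.approx(1.0)

    def test_cn_contingency_upper_bound(self):
        # the CN-alteration 2x2 reported for ALK-high 8/11 vs ALK-low 1/16
        assert sc.fisher_exact_2x2(8, 3, 1, 15).p_value <= 0.0198

    @pytest.mark.parametrize("table", [(8, 3, 1, 15), (2, 7, 8, 2),
                                       (0, 5, 5, 0), (3, 3, 3, 3)])
    def test_matches_enumeration_oracle_and_scipy(self, table):
        r = sc.fisher_exact_2x2(*table)
        assert r.p_value == pytest.approx(fisher_enumeration_oracle(*table),
                                          rel=1e-12)
        assert r.p_value == pytest.approx(
            sps.fisher_exact(np.array(table).reshape(2, 2))[1], rel=1e-9)

    def test_transposition_and_swap_invariance(self):
        p0 = sc.fisher_exact_2x2(8, 3, 1, 15).p_value
        assert sc.fisher_exact_2x2(8, 1, 3, 15).p_value == pytest.approx(p0)
        assert sc.fisher_exact_2x2(15, 1, 3, 8).p_value == pytest.approx(p0)

    def test_odds_ratio_and_validation(self):
        r = sc.fisher_exact_2x2(8, 3, 1, 15)
        assert r.extras["odds_ratio"] == pytest.approx(8 * 15 / 3)
        assert math.isinf(sc.fisher_exact_2x2(1, 0, 1, 1).extras["odds_ratio"])
        with pytest.raises(ValueError):
            sc.fisher_exact_2x2(-1, 1, 1, 1)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert sc.benjamini_hochberg([0.37])[0] == pytest.approx(0.37)

    def test_hand_worked_example(self):
        q = sc.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=40, deadline=None)
    def test_dominance_capping_and_order(self, ps):
        p = np.array(ps)
        q = sc.benjamini_hochberg(p)
        assert np.all(q >= p - 1e-12)
        assert q.max() <= 1.0
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(4)
        p = rng.uniform(size=97)
        assert np.allclose(sc.benjamini_hochberg(p),
                           multipletests(p, method="fdr_bh")[1])


class TestModeratedT:
    def test_equal_group_means_give_zero_t(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 8))
        X[0] = np.concatenate([[1, 2, 3, 4], [4, 3, 2, 1]])  # identical means
        _, t, p, _, _ = sc.moderated_t(X, np.arange(4), np.arange(4, 8))
        assert t[0] == pytest.approx(0.0, abs=1e-12)
        assert p[0] == pytest.approx(1.0)

    def test_formula_oracle_recovers_ranking(self):
        rng = np.random.default_rng(8)
        na = nb = 5
        X = rng.normal(0, rng.gamma(2, 0.6, size=(50, 1)) ** 0.5,
                       size=(50, na + nb))
        X[:10, :na] += 2.0
        lfc, t, p, dft, prior = sc.moderated_t(X, np.arange(na),
                                               np.arange(na, na + nb))
        # independent step-by-step application of the posterior formulas
        A, B = X[:, :na], X[:, na:]
        s2 = (A.var(axis=1, ddof=1) * (na - 1) +
              B.var(axis=1, ddof=1) * (nb - 1)) / (na + nb - 2)
        st_sq = (prior.d0 * prior.s0_sq + (na + nb - 2) * s2) / \
            (prior.d0 + na + nb - 2)
        t_oracle = (A.mean(axis=1) - B.mean(axis=1)) / \
            np.sqrt(st_sq * (1 / na + 1 / nb))
        assert np.allclose(t, t_oracle, atol=1e-10)
        assert list(np.argsort(-np.abs(t))) == list(np.argsort(-np.abs(t_oracle)))

    def test_infinite_prior_reduces_to_pooled_t_with_s0(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 10))
        # force exactly equal pooled variances so the prior dominates
        A, B = X[:, :5], X[:, 5:]
        s2 = (A.var(axis=1, ddof=1) * 4 + B.var(axis=1, ddof=1) * 4) / 8
        X = (X - X.mean(axis=1, keepdims=True)) / np.sqrt(s2)[:, None] \
            + X.mean(axis=1, keepdims=True)
        _, t, _, dft, prior = sc.moderated_t(X, np.arange(5), np.arange(5, 10))
        assert math.isinf(prior.d0)
        A2, B2 = X[:, :5], X[:, 5:]
        t_ref = (A2.mean(axis=1) - B2.mean(axis=1)) / \
            np.sqrt(prior.s0_sq * (1 / 5 + 1 / 5))
        assert np.allclose(t, t_ref, atol=1e-10)

    def test_zero_variance_feature_stays_finite(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 8))
        X[0] = 1.0
        _, t, p, _, _ = sc.moderated_t(X, np.arange(4), np.arange(4, 8))
        assert np.isfinite(t[0]) and np.isfinite(p[0])

    def test_matches_limma_ebayes(self, tmp_path):
        rng = np.random.default_rng(11)
        X = rng.normal(0, rng.gamma(3, 0.5, size=(80, 1)) ** 0.5,
                       size=(80, 12)) + 5
        mat = tmp_path / "m.tsv"
        np.savetxt(mat, X, delimiter="\t")
        out = tmp_path / "limma.tsv"
        script = f'''
        suppressMessages(library(limma))
        X <- as.matrix(read.table("{mat}"))
        design <- cbind(1, c(rep(1,6), rep(0,6)))
        fit <- eBayes(lmFit(X, design))
        write.table(cbind(fit$t[,2], fit$p.value[,2]), "{out}",
                    col.names=FALSE, row.names=FALSE)
        '''
        subprocess.run(["Rscript", "-e", script], check=True,
                       capture_output=True)
        L = np.loadtxt(out)
        _, t, p, _, _ = sc.moderated_t(X, np.arange(6), np.arange(6, 12))
        assert np.allclose(t, L[:, 0], atol=1e-8)
        assert np.allclose(p, L[:, 1], atol=1e-8)


class TestSignalToNoise:
    def test_direct_arithmetic(self):
        X = np.array([[1.0, 1.0, 0.0, 0.0]])
        # means 1 and 0, sds floored at 0.2*|mu| or 0.2 -> 0.2 each
        s = sc.signal_to_noise(X, [0, 1], [2, 3])
        assert s[0] == pytest.approx(1.0 / 0.4)

    def test_equal_means_zero_and_floor_keeps_finite(self):
        X = np.vstack([[2.0, 2.0, 2.0, 2.0], [5.0, 5.0, 5.0, 5.0]])
        s = sc.signal_to_noise(X, [0, 1], [2, 3])
        assert np.allclose(s, 0.0)
        X[1, :2] = 7.0                      # constant within each group
        s = sc.signal_to_noise(X, [0, 1], [2, 3])
        assert np.isfinite(s[1])
        assert s[1] == pytest.approx((7 - 5) / (0.2 * 7 + 0.2 * 5))


class TestSurvival:
    def test_all_censored_flat_curve(self):
        c = sc.km_estimate([1, 2, 3, 4], [0, 0, 0, 0])
        assert c.times.size == 0

    def test_hand_product_limit(self):
        c = sc.km_estimate([1, 2, 3], [1, 1, 1])
        assert np.allclose(c.survival, [2 / 3, 1 / 3, 0.0], atol=1e-10)
        assert list(c.at_risk) == [3, 2, 1]

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(3)
        c = sc.km_estimate(rng.exponential(5, 50), rng.integers(0, 2, 50))
        assert np.all(np.diff(c.survival) <= 1e-12)
        assert c.survival[0] <= 1.0

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(4)
        t = rng.exponential(5, 60)
        e = rng.integers(0, 2, 60)
        c = sc.km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ours = dict(zip(c.times, c.survival))
        for tt, s in ours.items():
            assert kmf.predict(tt) == pytest.approx(s, abs=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            sc.km_estimate([-1.0], [1])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 0, 1, 1, 0]
        g = [0, 0, 0, 1, 1, 1]
        r = sc.logrank_test(t, e, g)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_hand_computed_six_samples(self):
        # groups A: (1,e),(3,e),(5,c); B: (2,e),(4,e),(6,e)
        t = [1, 3, 5, 2, 4, 6]
        e = [1, 1, 0, 1, 1, 1]
        g = ["A", "A", "A", "B", "B", "B"]
        # event times 1,2,3,4,6: O_A-E_A and hypergeometric variances by hand
        o_e = (1 - 3 / 6) + (0 - 2 / 5) + (1 - 2 / 4) + (0 - 1 / 3) + (0 - 0)
        v = (3 * 3 * 5) / (36 * 5) + (2 * 3 * 4) / (25 * 4) + \
            (2 * 2 * 3) / (16 * 3) + (1 * 2 * 2) / (9 * 2) + 0.0
        r = sc.logrank_test(t, e, g)
        assert r.statistic == pytest.approx(o_e ** 2 / v, abs=1e-10)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll
        rng = np.random.default_rng(6)
        t = rng.exponential(4, 50)
        e = rng.integers(0, 2, 50)
        g = rng.integers(0, 2, 50)
        r = sc.logrank_test(t, e, g)
        ref = ll(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert r.statistic == pytest.approx(ref.test_statistic, abs=1e-9)
        assert r.p_value == pytest.approx(ref.p_value, abs=1e-9)

    def test_one_group_empty_errors(self):
        with pytest.raises(ValueError):
            sc.logrank_test([1, 2], [1, 1], [0, 0])
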