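import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracles import brute_bh, brute_concordance, grid_argmax_cox
from reo_prognosis import (bh_adjust, concordance_index, cox_fit,
                           cox_fit_multivariate, fisher_2x2, km_logrank, td_auc)
from reo_prognosis.survival_stats import cox_fit_binary_batch


class TestCoxFit:
    def test_constant_covariate_flagged_not_raised(self):
        fit = cox_fit([1.0] * 6, [1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 1, 0])
        assert not fit.converged
        assert fit.p == 1.0

    def test_fewer_than_two_events_flagged(self):
        fit = cox_fit([1, 2, 3, 4], [1, 2, 3, 4], [1, 0, 0, 0])
        assert not fit.converged and fit.p == 1.0

    def test_monotone_separation_has_unbounded_likelihood(self):
        # rank covariate perfectly anti-ordered with survival: the Breslow
        # partial likelihood is monotone in the coefficient, so there is no
        # finite maximizer; the fit must flag this instead of converging.
        time = np.arange(1.0, 7.0)
        x = time.copy()
        fit = cox_fit(x, time, np.ones(6))
        assert fit.coef < 0
        assert not fit.converged

    def test_binary_separation_positive_coef_and_perfect_concordance(self):
        # all x=1 samples die before any x=0 sample; times tied within each
        # group so every comparable pair crosses the groups
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        time = np.array([1, 1, 1, 1, 10, 10, 10, 10], dtype=float)
        event = np.ones(8)
        fit = cox_fit(x, time, event)
        assert fit.coef > 0
        assert concordance_index(x, time, event) == 1.0

    def test_coef_matches_grid_search_oracle(self, rng):
        """Newton solution equals the dense-grid Breslow-likelihood argmax."""
        checked = 0
        trial = 0
        while checked < 20:
            trial += 1
            n = 10
            local = np.random.default_rng(1000 + trial)
            x = local.standard_normal(n)
            beta_true = local.uniform(-1.2, 1.2)
            t = local.exponential(np.exp(-beta_true * x))
            if trial % 2 == 0:
                t = np.ceil(t * 4)  # force ties
            e = (local.random(n) < 0.85).astype(float)
            if e.sum() < 3:
                continue
            fit = cox_fit(x, t, e)
            if not fit.converged or abs(fit.coef) > 4.5:
                continue
            oracle = grid_argmax_cox(x, t, e)
            assert fit.coef == pytest.approx(oracle, abs=1e-3)
            checked += 1

    def test_hr_is_exp_coef_and_ci_brackets_hr(self, rng):
        x = rng.standard_normal(40)
        t = rng.exponential(10 * np.exp(-0.5 * x))
        fit = cox_fit(x, t, np.ones(40))
        assert fit.hr == pytest.approx(np.exp(fit.coef))
        assert fit.ci_low <= fit.hr <= fit.ci_high
        assert 0 <= fit.p <= 1

    def test_sign_agrees_with_concordance_direction(self):
        # For binary covariates with a clear effect, the Cox coefficient
        # sign and the concordance direction must agree. (Near the null
        # the two statistics weight pairs differently and may disagree,
        # so the check conditions on an informative fit.)
        checked = 0
        for seed in range(40):
            local = np.random.default_rng(seed)
            x = (local.random(30) < 0.5).astype(float)
            t = local.exponential(10 * np.exp(-0.8 * x))
            e = (local.random(30) < 0.8).astype(float)
            fit = cox_fit(x, t, e)
            if not fit.converged or fit.p > 0.05:
                continue
            c = concordance_index(x, t, e)
            assert (fit.coef > 0) == (c > 0.5)
            checked += 1
        assert checked >= 10

    def test_multivariate_returns_one_fit_per_covariate(self, rng):
        n = 60
        X = rng.standard_normal((n, 3))
        t = rng.exponential(10 * np.exp(-0.6 * X[:, 0]))
        fits = cox_fit_multivariate(X, t, np.ones(n))
        assert len(fits) == 3
        assert fits[0].coef > 0.2  # the only covariate carrying signal
        assert all(f.converged for f in fits)

    def test_binary_batch_agrees_with_single_fits(self, rng):
        n, m = 50, 8
        X01 = (rng.random((m, n)) < 0.5).astype(np.uint8)
        X01[0] = 0  # constant row must be flagged, not fitted
        t = rng.exponential(20, n)
        e = (rng.random(n) < 0.7).astype(float)
        res = cox_fit_binary_batch(X01, t, e)
        assert not res["converged"][0] and res["p"][0] == 1.0
        for i in range(1, m):
            single = cox_fit(X01[i].astype(float), t, e)
            assert res["coef"][i] == pytest.approx(single.coef, abs=1e-6)
            assert res["p"][i] == pytest.approx(single.p, abs=1e-6)


class TestConcordance:
    def test_perfect_score_gives_one(self):
        t = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        assert concordance_index(-t, t, np.ones(5)) == 1.0

    def test_all_ties_give_half(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert concordance_index(np.zeros(4), t, np.ones(4)) == 0.5

    def test_matches_brute_force_on_random_censored_instances(self):
        """200 random instances with censoring and ties: exact equality."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(4, 21))
            t = rng.integers(1, 8, n).astype(float)
            e = (rng.random(n) < 0.7).astype(float)
            s = rng.integers(0, 5, n).astype(float)
            try:
                expected = brute_concordance(s, t, e)
            except ValueError:
                with pytest.raises(ValueError):
                    concordance_index(s, t, e)
                continue
            assert concordance_index(s, t, e) == expected

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance_index([1.0, 2.0], [5.0, 5.0], [1.0, 1.0])

    @given(st.integers(0, 2 ** 31 - 1))
    def test_negation_complements_when_no_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        s = rng.permutation(n).astype(float)
        t = rng.permutation(n).astype(float) + 1
        e = (rng.random(n) < 0.7).astype(float)
        if e.sum() == 0:
            return
        c = concordance_index(s, t, e)
        assert concordance_index(-s, t, e) == pytest.approx(1.0 - c)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_invariant_under_increasing_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        s = rng.integers(-5, 6, n).astype(float)
        t = rng.integers(1, 9, n).astype(float)
        e = (rng.random(n) < 0.8).astype(float)
        if not ((t[:, None] < t[None, :]) & (e[:, None] == 1)).any():
            return
        base = concordance_index(s, t, e)
        assert concordance_index(3.0 * s + 7.0, t, e) == base


class TestBH:
    def test_single_p_identity(self):
        assert bh_adjust([0.03]).tolist() == [0.03]

    def test_hand_computed_example(self):
        # min over k>=i of p(k)*m/k: all collapse to 0.04
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            assert np.allclose(bh_adjust(p), brute_bh(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_dominates_raw_and_monotone_in_sorted_order(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestKMLogrank:
    def test_exchangeable_groups_give_p_one(self):
        t = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        e = np.array([1.0, 0, 1, 1, 1, 0, 1, 1])
        g = np.array(["a"] * 4 + ["b"] * 4)
        res = km_logrank(t, e, g)
        assert res.logrank_p == pytest.approx(1.0)
        np.testing.assert_allclose(res.curves["a"].to_numpy(),
                                   res.curves["b"].to_numpy())

    def test_separated_groups_significant(self):
        t = np.array([1.0, 2, 3, 10, 20, 30])
        e = np.ones(6)
        g = np.array(["a", "a", "a", "b", "b", "b"])
        assert km_logrank(t, e, g).logrank_p < 0.05

    def test_km_equals_empirical_survival_without_censoring(self):
        t = np.array([1.0, 2, 2, 3, 5])
        e = np.ones(5)
        res = km_logrank(np.r_[t, t], np.r_[e, e],
                         np.array(["a"] * 5 + ["b"] * 5))
        curve = res.curves["a"]
        # S(2) = 1 - 3/5, S(5) = 0: product-limit equals empirical fraction
        assert curve.loc[2.0].iloc[0] == pytest.approx(2 / 5)
        assert curve.iloc[-1, 0] == pytest.approx(0.0)

    def test_single_group_raises(self):
        with pytest.raises(ValueError, match="2 groups"):
            km_logrank([1.0, 2.0], [1, 1], ["a", "a"])


class TestFisher:
    def test_identical_rows_are_null(self):
        res = fisher_2x2(5, 5, 5, 5)
        assert res.odds_ratio == 1.0
        assert res.p == pytest.approx(1.0)

    def test_chemo_response_table(self):
        # low-risk 171 sensitive / 24 resistant vs high-risk 107 / 36;
        # expected values frozen from R fisher.test on the same table
        res = fisher_2x2(171, 24, 107, 36)
        assert round(res.odds_ratio, 3) == 2.397
        assert round(res.reciprocal_odds_ratio, 3) == 0.417
        assert res.p == pytest.approx(2.5246e-3, rel=1e-3)

    def test_platinum_response_table(self):
        res = fisher_2x2(157, 20, 100, 33)
        assert round(res.odds_ratio, 3) == 2.591
        assert round(res.reciprocal_odds_ratio, 3) == 0.386
        assert res.p == pytest.approx(2.2054e-3, rel=1e-3)

    def test_negative_cell_raises(self):
        with pytest.raises(ValueError):
            fisher_2x2(1, -1, 2, 3)

    @given(st.tuples(*[st.integers(1, 30)] * 4))
    def test_symmetries(self, cells):
        a, b, c, d = cells
        res = fisher_2x2(a, b, c, d)
        flipped = fisher_2x2(d, c, b, a)  # swap both rows and both columns
        assert flipped.p == pytest.approx(res.p)
        assert flipped.odds_ratio == pytest.approx(res.odds_ratio)
        row_swapped = fisher_2x2(c, d, a, b)
        assert row_swapped.odds_ratio == pytest.approx(1.0 / res.odds_ratio)


class TestTdAuc:
    def test_perfectly_separating_score(self):
        t = np.array([1.0, 2, 3, 20, 30, 40])
        s = np.array([9.0, 8, 7, 1, 2, 3])
        assert td_auc(s, t, np.ones(6), 10.0) == 1.0

    def test_constant_score_gives_half(self):
        t = np.array([1.0, 2, 3, 20, 30, 40])
        assert td_auc(np.ones(6), t, np.ones(6), 10.0) == 0.5

    def test_reduces_to_mann_whitney_without_censoring(self, rng):
        n = 10
        s = rng.standard_normal(n)
        t = rng.exponential(10, n)
        h = float(np.median(t))
        case = t <= h
        from scipy.stats import mannwhitneyu
        u = mannwhitneyu(s[case], s[~case]).statistic
        expected = u / (case.sum() * (~case).sum())
        assert td_auc(s, t, np.ones(n), h) == pytest.approx(expected)

    def test_matches_ipcw_reference_implementation(self, rng):
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv
        n = 100
        s = rng.standard_normal(n)
        te = rng.exponential(20 * np.exp(-0.5 * s))
        tc = rng.exponential(40, n)
        time = np.minimum(te, tc)
        event = te <= tc
        y = Surv.from_arrays(event, time)
        for h in (10.0, 25.0):
            ref = cumulative_dynamic_auc(y, y, s, [h])[0][0]
            assert td_auc(s, time, event.astype(float), h) == pytest.approx(ref)

    def test_no_cases_raises_naming_horizon(self):
        t = np.array([10.0, 20, 30])
        with pytest.raises(ValueError, match="5.0"):
            td_auc(np.ones(3), t, np.ones(3), 5.0)
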