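import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from mbsvkit.enrichment import (
    bh_fdr,
    fisher_exact,
    ks_two_sample,
    neglog10,
    quantile_regression_binary,
    rank_compare,
    threshold_enrichment,
)


def brute_force_ks_d(x, y):
    """Maximal ECDF gap scanned at every data point."""
    pts = np.concatenate([x, y])
    gaps = [abs((x <= t).mean() - (y <= t).mean()) for t in pts]
    return max(gaps)


def exhaustive_fisher_p(a, b, c, d):
    """Independent oracle: exact rational sum over all tables with the margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    ws = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    w_obs = ws[a - lo]
    return Fraction(sum(w for w in ws if w <= w_obs), math.comb(n, c1))


class TestKsTwoSample:
    def test_identical_samples_have_zero_distance(self):
        x = np.array([1.0, 2.0, 3.0, 3.0])
        d, p = ks_two_sample(x, x.copy())
        assert d == 0.0

    def test_disjoint_supports_have_distance_one(self):
        d, _ = ks_two_sample([1, 2, 3], [10, 11])
        assert d == pytest.approx(1.0)

    def test_matches_brute_force_gap_scan(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([1.5, 2.5])
        d, _ = ks_two_sample(x, y)
        assert d == pytest.approx(brute_force_ks_d(x, y), abs=1e-12)

    def test_brute_force_oracle_on_random_samples(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            x = rng.normal(size=rng.integers(2, 15))
            y = rng.normal(size=rng.integers(2, 15))
            d, _ = ks_two_sample(x, y)
            assert d == pytest.approx(brute_force_ks_d(x, y), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestFisherExact:
    def test_empty_success_margin_is_uninformative(self):
        res = fisher_exact(0, 10, 0, 10)
        assert res.p == 1.0 and math.isnan(res.odds_ratio)

    def test_oracle_equivalence_small_sweep(self):
        """Exact rational enumeration agrees for every table with total <= 15."""
        for n in range(1, 16):
            for r1 in range(n + 1):
                r2 = n - r1
                for c1 in range(n + 1):
                    lo, hi = max(0, c1 - r2), min(r1, c1)
                    for a in range(lo, hi + 1):
                        b, c = r1 - a, c1 - a
                        d = r2 - c
                        got = fisher_exact(a, b, c, d, with_odds_ratio=False).p
                        want = exhaustive_fisher_p(a, b, c, d)
                        assert got == pytest.approx(float(want), rel=1e-12), (a, b, c, d)

    def test_agrees_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 40, size=4)
            ours = fisher_exact(int(a), int(b), int(c), int(d))
            theirs = stats.fisher_exact([[a, b], [c, d]])
            if (a + c) and (b + d) and (a + b) and (c + d):
                assert ours.p == pytest.approx(theirs.pvalue, rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(-1, 2, 3, 4)

    def test_conditional_mle_differs_from_sample_or(self):
        res = fisher_exact(9, 3207, 1, 3326)
        assert res.odds_ratio == pytest.approx(9.3316, abs=2e-4)
        assert res.sample_odds_ratio == pytest.approx(9.3340, abs=2e-4)


class TestThresholdEnrichment:
    def test_counts_match_truth_recount(self):
        rng = np.random.default_rng(3)
        p1 = rng.uniform(size=500)
        p0 = rng.uniform(size=800)
        res = threshold_enrichment(p1, p0, thresholds=(0.01, 0.05))
        for r in res:
            assert r.n_hits_1 == (p1 < r.threshold).sum()
            assert r.n_hits_0 == (p0 < r.threshold).sum()
            assert r.proportion_1 == pytest.approx(r.n_hits_1 / 500)

    def test_no_hits_gives_p_one(self):
        res = threshold_enrichment([0.5] * 10, [0.6] * 10, thresholds=(1e-5,))
        assert res[0].fisher.p == 1.0

    def test_threshold_range_enforced(self):
        with pytest.raises(ValueError):
            threshold_enrichment([0.5], [0.5], thresholds=(1.5,))


class TestQuantileRegressionBinary:
    def test_translation_recovers_shift_at_every_quantile(self):
        rng = np.random.default_rng(4)
        y0 = rng.normal(size=151)
        c = 0.8
        y = np.concatenate([y0, y0 + c])
        x = np.repeat([False, True], 151)
        for tau in (0.5, 0.9, 0.99):
            res = quantile_regression_binary(y, x, tau, n_boot=20, seed=1)
            assert res.coef == pytest.approx(c, abs=1e-12)

    def test_identical_groups_have_zero_coefficient(self):
        y0 = np.arange(50, dtype=float)
        y = np.concatenate([y0, y0])
        x = np.repeat([False, True], 50)
        assert quantile_regression_binary(y, x, 0.5, n_boot=20, seed=2).coef == 0.0

    def test_group_quantile_identity(self):
        """Coefficient equals the within-group check-loss quantile difference."""
        rng = np.random.default_rng(5)
        y = rng.normal(size=301)
        x = rng.random(301) < 0.4
        for tau in (0.5, 0.9, 0.999):
            res = quantile_regression_binary(y, x, tau, n_boot=10, seed=3)
            q1 = _brute_force_check_loss_quantile(y[x], tau)
            q0 = _brute_force_check_loss_quantile(y[~x], tau)
            assert res.coef == pytest.approx(q1 - q0, abs=1e-10)

    def test_agrees_with_statsmodels_quantreg(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        y = np.concatenate([rng.normal(size=101), rng.normal(0.5, 1, size=101)])
        x = np.repeat([0.0, 1.0], 101)
        ours = quantile_regression_binary(y, x.astype(bool), 0.5, n_boot=10, seed=4)
        sm_fit = sm.QuantReg(y, sm.add_constant(x)).fit(q=0.5)
        assert ours.coef == pytest.approx(sm_fit.params[1], abs=1e-4)

    def test_bootstrap_se_recovers_known_shift(self):
        rng = np.random.default_rng(7)
        shift = 0.6
        y = np.concatenate([rng.normal(size=200), rng.normal(shift, 1, size=200)])
        x = np.repeat([False, True], 200)
        res = quantile_regression_binary(y, x, 0.5, n_boot=200, seed=8)
        assert abs(res.coef - shift) <= 3 * res.se
        res2 = quantile_regression_binary(y, x, 0.5, n_boot=200, seed=9)
        assert res2.se == pytest.approx(res.se, rel=0.25)

    def test_both_classes_required(self):
        with pytest.raises(ValueError):
            quantile_regression_binary([1.0, 2.0], [True, True], 0.5)


def _brute_force_check_loss_quantile(v, tau):
    """Smallest minimizer of the check loss over the data values."""
    def loss(q):
        r = v - q
        return np.sum(np.where(r >= 0, tau * r, (tau - 1) * r))
    cands = np.sort(np.unique(v))
    losses = np.array([loss(q) for q in cands])
    return cands[np.argmin(losses)]  # argmin returns the first (smallest)


class TestBhFdr:
    def test_single_p_is_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_step_up_formula(self):
        assert bh_fdr([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_equal_ps_are_unchanged(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_dominates_raw_p_and_monotone(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        assert np.all(q >= p) and np.all(q <= 1)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestRankCompare:
    def test_planted_shift_recovers_sign(self):
        rng = np.random.default_rng(10)
        scores = np.concatenate([rng.normal(1.0, 1, 300), rng.normal(0, 1, 300)])
        subset = np.repeat([True, False], 300)
        res = rank_compare(scores, subset, n_boot=50, seed=11)
        assert res.median_reg.coef > 0
        assert res.ks_p < 0.01

    def test_identical_distributions_give_small_d(self):
        vals = np.tile(np.arange(100, dtype=float), 2)
        subset = np.repeat([True, False], 100)
        res = rank_compare(vals, subset, n_boot=20, seed=12)
        assert res.ks_d == pytest.approx(0.0, abs=1e-12)

    def test_constant_scores_reported_as_degenerate(self):
        res = rank_compare(np.ones(10), np.arange(10) < 5)
        assert res.degenerate and res.ks_d == 0.0 and res.median_reg is None


def test_neglog10_floors_small_p():
    out = neglog10([1.0, 1e-310, 0.0])
    assert out[0] == 0.0 and np.isfinite(out).all() and out[2] == 300.0
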