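"""Statistical battery: formula oracles, enumeration oracles, calibration."""

import itertools
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from synaptostats3d import stats_engine as se


class TestChi2:
    def test_uniform_table_statistic_zero(self):
        res = se.chi2_contingency([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_printed_formula_example(self):
        # all E_ij = 15 -> statistic 4 * 25/15 = 6.667 on 1 df
        res = se.chi2_contingency([[10, 20], [20, 10]])
        assert res.statistic == pytest.approx(4 * 25 / 15)
        assert round(res.statistic, 3) == 6.667
        assert res.df == 1

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(0)
        tab = rng.integers(5, 200, size=(3, 4))
        ours = se.chi2_contingency(tab)
        ref = sps.chi2_contingency(tab, correction=False)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            se.chi2_contingency([[0, 0], [0, 0]])

    @given(st.lists(st.lists(st.integers(0, 50), min_size=2, max_size=4),
                    min_size=2, max_size=4).filter(
               lambda t: len({len(r) for r in t}) == 1 and sum(map(sum, t)) > 0))
    def test_expected_frequencies_reproduce_margins(self, table):
        tab = np.array(table, float)
        exp = se.expected_frequencies(tab)
        np.testing.assert_allclose(exp.sum(axis=1), tab.sum(axis=1))
        np.testing.assert_allclose(exp.sum(axis=0), tab.sum(axis=0))

    def test_statistic_invariant_under_permutation(self):
        tab = np.array([[12, 7, 30], [5, 22, 9]])
        base = se.chi2_contingency(tab).statistic
        assert se.chi2_contingency(tab[::-1]).statistic == pytest.approx(base)
        assert se.chi2_contingency(tab[:, ::-1]).statistic == pytest.approx(base)


def _mw_enumeration_p(x, y):
    """Exhaustive rank-permutation two-sided Mann-Whitney p-value."""
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = np.array([ranks[list(c)].sum() - n * (n + 1) / 2
                   for c in itertools.combinations(range(n + m), n)])
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)


class TestRankTests:
    def test_identical_samples_trivial(self):
        x = np.arange(10.0)
        assert se.ks_two_sample(x, x).statistic == 0.0
        assert se.mann_whitney(x, x + 0.0).p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_mw_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=int(rng.integers(3, 9)))
        y = rng.normal(0.8, size=int(rng.integers(3, 9)))
        ours = se.mann_whitney(x, y).p_value
        assert ours == pytest.approx(_mw_enumeration_p(x, y), abs=1e-9)

    def test_ks_power_on_shifted_samples(self):
        # 2-SD shift at n = 500 per sample is detected essentially always
        rejections = 0
        for i in range(20):
            rng = np.random.default_rng(100 + i)
            res = se.ks_two_sample(rng.normal(0, 1, 500), rng.normal(2, 1, 500))
            rejections += res.p_value < 0.001
        assert rejections == 20

    def test_anova_equal_means_f_near_zero(self):
        groups = {k: np.array([1.0, 2.0, 3.0, 4.0]) for k in "abc"}
        res, pair = se.anova_tukey(groups)
        assert res.statistic == pytest.approx(0.0)
        assert len(pair) == 3

    def test_anova_detects_separated_groups(self):
        rng = np.random.default_rng(1)
        groups = {"a": rng.normal(0, 1, 8), "b": rng.normal(5, 1, 8)}
        res, pair = se.anova_tukey(groups)
        assert res.significant
        assert bool(pair["reject"].iloc[0])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            se.mann_whitney([], [1.0])


class TestDualThreshold:
    def test_alpha_selection(self):
        assert se.alpha_for_basis("subjects") == 0.05
        assert se.alpha_for_basis("synapses") == 0.001
        with pytest.raises(ValueError):
            se.alpha_for_basis("stacks")

    def test_significance_follows_basis(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 300), rng.normal(0.25, 1, 300)
        res = sps.ks_2samp(x, y)
        mid_p = res.pvalue
        assert 0.001 < mid_p < 0.05  # chosen effect size sits between thresholds
        assert se.ks_two_sample(x, y, n_basis="subjects").significant
        assert not se.ks_two_sample(x, y, n_basis="synapses").significant


class TestSizeFits:
    def test_lognormal_mle_recovery(self):
        mu, sigma, n = 11.0, 0.9, 5_000
        rng = np.random.default_rng(3)
        x = rng.lognormal(mu, sigma, n)
        fit = se.fit_size_distribution(x, "lognormal")
        assert abs(fit.params["mu"] - mu) < 3 * sigma / math.sqrt(n)
        assert abs(fit.params["sigma"] - sigma) < 3 * sigma / math.sqrt(2 * n)
        assert fit.ks_distance < 0.05

    def test_aic_prefers_generating_family(self):
        wins = 0
        for i in range(100):
            rng = np.random.default_rng(500 + i)
            x = rng.lognormal(11.0, 0.8, 400)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ln = se.fit_size_distribution(x, "lognormal")
                ll = se.fit_size_distribution(x, "loglogistic")
            wins += ln.aic < ll.aic
        assert wins >= 90

    def test_loglogistic_parameterization(self):
        # CDF(alpha) = 1/2: alpha is the median
        rng = np.random.default_rng(4)
        alpha, beta = 80_000.0, 4.0
        u = rng.uniform(size=20_000)
        x = alpha * (u / (1 - u)) ** (1 / beta)
        fit = se.fit_size_distribution(x, "loglogistic")
        assert fit.params["alpha"] == pytest.approx(alpha, rel=0.05)
        assert fit.params["beta"] == pytest.approx(beta, rel=0.05)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            se.fit_size_distribution(np.full(100, 7.0), "lognormal")
        with pytest.raises(ValueError):
            se.fit_size_distribution(-np.ones(100), "lognormal")


class TestRSquared:
    def test_perfect_line(self):
        x = np.arange(10.0)
        assert se.r_squared(x, 2 * x + 1) == pytest.approx(1.0)

    def test_negative_slope_still_one(self):
        x = np.arange(10.0)
        assert se.r_squared(x, -x + 3) == pytest.approx(1.0)

    def test_four_point_formula_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        y = np.array([2.0, 3.0, 3.5, 8.0])
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        expected = sxy ** 2 / (((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert se.r_squared(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            se.r_squared(np.ones(5), np.arange(5.0))
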