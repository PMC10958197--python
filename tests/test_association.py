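"""Trend test, genotypic Fisher exact, allelic OR, logistic association."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prsresponse.association import (
    SeparationError,
    allelic_odds_ratio,
    fisher_exact_genotypic,
    fit_logistic,
    trend_test,
    univariate_screen,
)


def trend_oracle(r, s):
    """Independent oracle: Cochran-Armitage statistic equals N * corr^2 of
    genotype score vs group indicator over expanded individual-level data."""
    xs = np.concatenate([np.repeat([0, 1, 2], r), np.repeat([0, 1, 2], s)])
    ys = np.concatenate([np.ones(int(np.sum(r))), np.zeros(int(np.sum(s)))])
    rho = np.corrcoef(xs, ys)[0, 1]
    chi2 = len(xs) * rho**2
    return chi2, stats.chi2.sf(chi2, df=1)


class TestTrendTest:
    def test_identical_proportions_zero(self):
        chi2, p = trend_test([30, 20, 10], [60, 40, 20])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_maximal_trend_matches_oracle(self):
        chi2, p = trend_test([0, 0, 50], [50, 0, 0])
        o_chi2, o_p = trend_oracle([0, 0, 50], [50, 0, 0])
        assert chi2 == pytest.approx(o_chi2)
        assert p == pytest.approx(o_p)

    def test_cohort_table_counts_match_oracle_to_4dp(self):
        # responder vs non-responder genotype counts for one panel SNP
        chi2, p = trend_test([157, 76, 16], [146, 56, 10])
        o_chi2, o_p = trend_oracle([157, 76, 16], [146, 56, 10])
        assert round(chi2, 4) == round(o_chi2, 4)
        assert round(p, 4) == round(o_p, 4)

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            r = rng.integers(1, 80, 3)
            s = rng.integers(1, 80, 3)
            chi2, _ = trend_test(r, s)
            assert chi2 == pytest.approx(trend_oracle(r, s)[0])

    def test_genotype_relabel_invariance(self):
        a, b = [20, 30, 10], [15, 25, 30]
        assert trend_test(a, b)[0] == pytest.approx(trend_test(a[::-1], b[::-1])[0])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            trend_test([0, 0, 0], [10, 10, 10])


def fisher_oracle(case_counts, control_counts):
    """Independent enumeration with binomial-coefficient arithmetic."""
    obs = np.array([case_counts, control_counts]).T
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    n = obs.sum()
    denom = math.comb(n, col[0])

    def prob(a, b, c):
        return (
            math.comb(row[0], a) * math.comb(row[1], b) * math.comb(row[2], c)
        ) / denom

    p_obs = prob(obs[0, 0], obs[1, 0], obs[2, 0])
    total = 0.0
    for a, b in itertools.product(range(row[0] + 1), range(row[1] + 1)):
        c = col[0] - a - b
        if c < 0 or c > row[2]:
            continue
        pr = prob(a, b, c)
        if pr <= p_obs * (1 + 1e-9):
            total += pr
    return min(total, 1.0)


class TestFisherExact:
    def test_minimal_table_matches_enumeration(self):
        assert fisher_exact_genotypic([1, 0, 0], [0, 0, 1]) == pytest.approx(
            fisher_oracle([1, 0, 0], [0, 0, 1])
        )

    def test_identical_columns_p_one(self):
        assert fisher_exact_genotypic([5, 5, 5], [5, 5, 5]) == pytest.approx(1.0)

    def test_random_small_tables_match_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            r = rng.integers(0, 8, 3)
            s = rng.integers(0, 8, 3)
            if r.sum() == 0 or s.sum() == 0:
                continue
            got = fisher_exact_genotypic(r, s)
            assert got == pytest.approx(fisher_oracle(r, s), abs=1e-12)
            assert 0.0 < got <= 1.0

    def test_2x2_margin_agrees_with_scipy(self):
        # collapsing the middle genotype row to zero reduces to a 2x2 table
        p = fisher_exact_genotypic([8, 0, 2], [3, 0, 7])
        _, p_scipy = stats.fisher_exact([[8, 2], [3, 7]])
        assert p == pytest.approx(p_scipy)

    def test_enumeration_limit_enforced(self):
        with pytest.raises(ValueError, match="Monte-Carlo"):
            fisher_exact_genotypic([4000, 0, 0], [4000, 0, 0], max_n=100)


class TestAllelicOR:
    def test_balanced_table_or_one(self):
        res = allelic_odds_ratio([5, 0, 5], [5, 0, 5])  # alleles 10/10 vs 10/10
        assert res.odds_ratio == pytest.approx(1.0)

    def test_woolf_ci_hand_arithmetic(self):
        res = allelic_odds_ratio([5, 0, 10], [10, 0, 5])  # alleles 20/10 vs 10/20
        assert res.odds_ratio == pytest.approx(4.0)
        se = math.sqrt(1 / 20 + 1 / 10 + 1 / 10 + 1 / 20)
        assert res.ci_low == pytest.approx(4.0 * math.exp(-1.96 * se))
        assert res.ci_high == pytest.approx(4.0 * math.exp(1.96 * se))

    def test_group_swap_inverts_or_exactly(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            r = rng.integers(1, 50, 3)
            s = rng.integers(1, 50, 3)
            a = allelic_odds_ratio(r, s).odds_ratio
            b = allelic_odds_ratio(s, r).odds_ratio
            assert a * b == pytest.approx(1.0)

    def test_zero_cell_haldane_flagged(self):
        res = allelic_odds_ratio([10, 0, 0], [0, 0, 10])
        assert "haldane_correction" in res.flags
        assert np.isfinite(res.odds_ratio)


class TestFitLogistic:
    def test_null_prs_or_near_one(self):
        rng = np.random.default_rng(12)
        n = 5000
        prs = rng.normal(6, 2, n)
        y = rng.random(n) < 0.5
        res = fit_logistic(y, pd.DataFrame({"score": prs}))["score"]
        assert 0.94 < res.odds_ratio < 1.06
        assert res.p > 0.01

    def test_recovers_known_effect_within_3se(self):
        rng = np.random.default_rng(13)
        n = 2000
        prs = rng.normal(6, 2, n)
        beta = math.log(1.25)
        p = 1 / (1 + np.exp(-(0.1 + beta * (prs - 6))))
        y = rng.random(n) < p
        res = fit_logistic(y, pd.DataFrame({"score": prs}))["score"]
        assert abs(res.beta - beta) < 3 * res.se

    def test_wald_ci_brackets_or(self):
        rng = np.random.default_rng(14)
        prs = rng.normal(0, 1, 500)
        y = rng.random(500) < 0.5
        res = fit_logistic(y, pd.DataFrame({"x": prs}))["x"]
        assert res.ci_low <= res.odds_ratio <= res.ci_high

    def test_perfect_separation_raises(self):
        rng = np.random.default_rng(15)
        prs = rng.normal(0, 1, 200)
        y = (prs > np.median(prs)).astype(int)
        with pytest.raises(SeparationError):
            fit_logistic(y, pd.DataFrame({"x": prs}))

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))

    def test_missing_design_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(
                np.array([0, 1, 0, 1.0]), pd.DataFrame({"x": [1.0, np.nan, 2.0, 3.0]})
            )


class TestUnivariateScreen:
    def test_real_age_effect_flagged(self):
        rng = np.random.default_rng(16)
        n = 800
        age = rng.uniform(18, 80, n)
        p = 1 / (1 + np.exp(-(1.2 - 0.03 * age)))
        y = rng.random(n) < p
        out = univariate_screen(pd.DataFrame({"age": age}), y)
        assert bool(out.loc[out["covariate"] == "age", "selected"].iloc[0])

    def test_constant_covariate_skipped(self):
        y = np.array([0, 1, 0, 1])
        out = univariate_screen(pd.DataFrame({"c": [3.0, 3.0, 3.0, 3.0]}), y)
        assert out["flag"].iloc[0] == "constant_skipped"
        assert not out["selected"].iloc[0]

    def test_noise_covariate_false_positive_rate(self):
        # nominal 5% selection rate for pure noise, +/- 2 MC SEs
        rng = np.random.default_rng(17)
        reps, n = 400, 150
        hits = 0
        y = rng.integers(0, 2, size=(reps, n))
        x = rng.normal(size=(reps, n))
        for i in range(reps):
            if y[i].min() == y[i].max():
                continue
            out = univariate_screen(pd.DataFrame({"z": x[i]}), y[i])
            hits += int(out["selected"].iloc[0])
        rate = hits / reps
        se = math.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se
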