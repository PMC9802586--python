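"""Statistical battery against enumeration / closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from fatvt.stats import (
    anova_unbalanced,
    fisher_or,
    linear_regression_adjusted,
    pearson_r,
    poisson_regression,
    unpaired_t,
)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        f, p = anova_unbalanced([1.0, 1.0, 1.0], [1.0, 1.0])
        assert f == 0.0

    def test_hand_computed_f(self):
        # groups {1,2,3} vs {7,8,9}: SSB=54 (df 1), SSW=4 (df 4) -> F=54
        f, p = anova_unbalanced([1, 2, 3], [7, 8, 9])
        assert f == pytest.approx(54.0)
        assert 0 < p < 0.01

    def test_null_p_uniformish_under_permutation(self, rng):
        vals = rng.normal(size=40)
        ps = []
        for _ in range(300):
            perm = rng.permutation(vals)
            _, p = anova_unbalanced(perm[:13], perm[13:27], perm[27:])
            ps.append(p)
        ps = np.asarray(ps)
        # roughly uniform: ~10% below 0.1, ~50% below 0.5
        assert 0.04 < np.mean(ps < 0.1) < 0.2
        assert 0.35 < np.mean(ps < 0.5) < 0.65

    def test_validation(self):
        with pytest.raises(ValueError):
            anova_unbalanced([1.0])


class TestFisher:
    def test_symmetric_table(self):
        res = fisher_or([[10, 10], [10, 10]])
        assert res["odds_ratio"] == pytest.approx(1.0)

    def test_sample_or_is_ad_over_bc(self):
        res = fisher_or([[20, 10], [10, 20]])
        assert res["odds_ratio"] == pytest.approx(4.0)

    def test_p_matches_hypergeometric_enumeration(self):
        a, b, c, d = 3, 7, 8, 2
        res = fisher_or([[a, b], [c, d]])
        # enumerate all tables with the same margins; two-sided p sums the
        # probabilities of tables at most as probable as the observed one
        r1, r2 = a + b, c + d
        c1 = a + c
        def prob(x):
            return (comb(r1, x) * comb(r2, c1 - x)) / comb(r1 + r2, c1)
        p_obs = prob(a)
        p_exact = sum(
            prob(x)
            for x in range(max(0, c1 - r2), min(r1, c1) + 1)
            if prob(x) <= p_obs * (1 + 1e-9)
        )
        assert res["p"] == pytest.approx(p_exact, rel=1e-6)

    def test_zero_margin_flagged(self):
        res = fisher_or([[5, 0], [3, 2]])
        assert res["undefined"]

    def test_transposition_invariance_and_row_swap(self):
        t = [[12, 5], [7, 9]]
        assert fisher_or(t)["p"] == pytest.approx(
            fisher_or(np.transpose(t))["p"]
        )
        swapped = fisher_or(t[::-1])
        assert swapped["odds_ratio"] == pytest.approx(
            1.0 / fisher_or(t)["odds_ratio"]
        )

    def test_ci_methods(self):
        res_l = fisher_or([[20, 10], [10, 20]], ci_method="logit")
        assert res_l["ci_method"] == "logit"
        assert res_l["ci"][0] < 4.0 < res_l["ci"][1]
        res_c = fisher_or([[20, 10], [10, 20]])
        assert res_c["ci"][0] < 4.0 < res_c["ci"][1]


class TestPoissonRegression:
    def test_null_predictor_gives_zero_percent(self, rng):
        counts = rng.poisson(3.0, size=2000)
        preds = pd.DataFrame({"x": rng.normal(size=2000)})
        res = poisson_regression(counts, preds)
        assert abs(res.percent_per_increment["x"]) < 12.0
        assert res.pvalues["x"] > 0.001

    def test_recovers_generator_rate_ratio(self, rng):
        x = rng.uniform(0, 40, size=3000)
        b = np.log(1.10) / 5.55
        counts = rng.poisson(np.exp(0.8 + b * x))
        res = poisson_regression(counts, pd.DataFrame({"x": x}))
        assert res.percent_per_increment["x"] == pytest.approx(10.0, abs=2.0)
        # reported rate ratio is exp(beta * increment)
        assert res.rate_ratios["x"] == pytest.approx(
            np.exp(res.params["x"] * 5.55)
        )

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            poisson_regression([1.5, 2.0], pd.DataFrame({"x": [1.0, 2.0]}))


class TestLinearRegression:
    def test_exact_linear_fit(self):
        x = np.arange(10.0)
        res = linear_regression_adjusted(3.0 * x + 1.0, x)
        assert res.params["exposure"] == pytest.approx(3.0)
        assert res.model.resid.max() == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations_on_hand_data(self):
        y = np.array([2.0, 4.1, 5.9, 8.2, 9.8, 12.1])
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        z = np.array([0.3, -0.1, 0.4, 0.0, -0.2, 0.1])
        X = np.column_stack([np.ones(6), x, z])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        res = linear_regression_adjusted(y, x, pd.DataFrame({"z": z}))
        assert res.params["exposure"] == pytest.approx(beta[1])
        assert res.params["z"] == pytest.approx(beta[2])

    def test_orthogonal_covariate_leaves_exposure_unchanged(self, rng):
        x = np.arange(20.0) - 9.5
        y = 2.0 * x + rng.normal(size=20)
        z = np.cos(np.linspace(0, 2 * np.pi, 20, endpoint=False))
        z = z - z.mean()
        z = z - (z @ x) / (x @ x) * x  # orthogonalize
        b0 = linear_regression_adjusted(y, x).params["exposure"]
        b1 = linear_regression_adjusted(y, x, pd.DataFrame({"z": z}))
        assert b1.params["exposure"] == pytest.approx(b0)


class TestSimpleStats:
    def test_pearson_perfect_and_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r, _ = pearson_r(x, 2 * x)
        assert r == pytest.approx(1.0)
        y = np.array([2.1, 1.9, 3.5, 3.9, 5.2])
        r, _ = pearson_r(x, y)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        oracle = cov / (x.std() * y.std())
        assert r == pytest.approx(oracle)

    def test_t_identical_groups(self):
        t, p = unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            unpaired_t([1.0], [2.0, 3.0])


def test_poisson_ci_coverage_near_nominal():
    """95% Wald CIs for the rate coefficient cover the truth ~95% of the
    time over replicated synthetic cohorts."""
    rng = np.random.default_rng(77)
    b_true = np.log(1.10) / 5.55
    hits = 0
    n_rep = 200
    for _ in range(n_rep):
        x = rng.uniform(0, 40, size=250)
        counts = rng.poisson(np.exp(0.8 + b_true * x))
        res = poisson_regression(counts, pd.DataFrame({"x": x}))
        lo, hi = res.conf_int.loc["x"]
        hits += lo <= b_true <= hi
    assert 0.90 <= hits / n_rep <= 0.99
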