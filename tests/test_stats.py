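"""Inference layer: change tests, regressions, mediation.

Oracles: statsmodels AnovaRM for the repeated-measures identity, scipy
two-sample t for the interaction identity, pingouin's mediation routine
as an independent cross-check of the path estimates, and Monte-Carlo
simulations with known truth for recovery checks.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from svdnet.stats import (
    adjusted_group_difference,
    fit_mediation,
    group_time_interaction,
    log_transform_wmh,
    median_split,
    paired_change_test,
    standardized_regression,
)


class TestPairedChangeTest:
    def test_identical_waves(self):
        v = np.arange(10.0)
        res = paired_change_test(v, v)
        assert res.mean_difference == 0.0
        assert res.p_value == 1.0

    def test_estimate_inside_own_ci(self):
        rng = np.random.default_rng(0)
        b = rng.normal(0, 1, 50)
        f = b + rng.normal(-0.4, 1.0, 50)
        res = paired_change_test(b, f)
        assert res.ci95[0] <= res.mean_difference <= res.ci95[1]
        assert res.n == 50

    def test_matches_scipy_paired_t(self):
        rng = np.random.default_rng(1)
        b, f = rng.normal(size=(2, 30))
        res = paired_change_test(b, f)
        t, p = sps.ttest_rel(f, b)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_rm_anova_f_equals_t_squared(self):
        """Two-level repeated-measures ANOVA F == paired t^2 (AnovaRM oracle)."""
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            b = rng.normal(0, 2, n)
            f = b + rng.normal(-0.3, 1.0, n)
            res = paired_change_test(b, f)
            d = res.mean_difference
            se = (f - b).std(ddof=1) / np.sqrt(n)
            t2 = (d / se) ** 2
            long = pd.DataFrame({
                "subject": np.tile(np.arange(n), 2),
                "wave": np.repeat(["b", "f"], n),
                "y": np.concatenate([b, f]),
            })
            aov = AnovaRM(long, "y", "subject", within=["wave"]).fit()
            F = float(aov.anova_table["F Value"].iloc[0])
            assert F == pytest.approx(t2, abs=1e-8 * max(1, t2))
            assert float(aov.anova_table["Pr > F"].iloc[0]) == pytest.approx(
                res.p_value, abs=1e-8
            )

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3"):
            paired_change_test([1.0, 2.0], [1.5, 2.5])

    def test_coverage_of_true_shift(self):
        """95% CI covers the simulated true change in ~95% of replicates."""
        rng = np.random.default_rng(3)
        hits = 0
        reps = 300
        for _ in range(reps):
            b = rng.normal(0, 1, 270)
            f = b + rng.normal(-0.44, 1.5, 270)
            res = paired_change_test(b, f)
            hits += res.ci95[0] <= -0.44 <= res.ci95[1]
        assert hits / reps >= 0.93


class TestGroupTimeInteraction:
    def test_equals_two_sample_t_on_deltas(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(8, 60))
            b = rng.normal(size=n)
            f = b + rng.normal(size=n)
            g = rng.choice(["x", "y"], size=n)
            if min((g == "x").sum(), (g == "y").sum()) < 3:
                continue
            p_int = group_time_interaction(b, f, g)
            d = f - b
            _, p_t = sps.ttest_ind(d[g == "x"], d[g == "y"], equal_var=True)
            assert p_int == pytest.approx(p_t, abs=1e-8)

    def test_power_against_differential_decline(self):
        rng = np.random.default_rng(5)
        sig = 0
        reps = 100
        for _ in range(reps):
            n = 100
            b = np.concatenate([rng.normal(0, 1, n), rng.normal(0, 1, n)])
            delta = np.concatenate([rng.normal(-0.3, 0.5, n), rng.normal(0, 0.5, n)])
            g = np.repeat(["decl", "stab"], n)
            sig += group_time_interaction(b, b + delta, g) < 0.05
        assert sig / reps >= 0.80

    def test_small_group_rejected(self):
        b = np.zeros(5)
        f = np.ones(5)
        with pytest.raises(ValueError, match="fewer than 3"):
            group_time_interaction(b, f, np.array(["a", "a", "a", "a", "b"]))


class TestAdjustedGroupDifference:
    def test_orthogonal_covariate_leaves_difference(self):
        rng = np.random.default_rng(6)
        n = 200
        g = np.repeat(["ctl", "pat"], n // 2)
        cov = rng.normal(size=n)  # independent of group
        y = 2.0 * (g == "pat") + 0.5 * cov + rng.normal(0, 0.1, n)
        res = adjusted_group_difference(y, g, pd.DataFrame({"c": cov}))
        assert res.mean_difference == pytest.approx(2.0, abs=0.1)

    def test_covariate_only_outcome_gives_null_group_effect(self):
        rng = np.random.default_rng(7)
        n = 300
        g = rng.choice(["a", "b"], n)
        cov = rng.normal(size=n)
        y = 1.5 * cov + rng.normal(0, 0.2, n)
        res = adjusted_group_difference(y, g, pd.DataFrame({"c": cov}))
        assert abs(res.mean_difference) < 0.15
        assert res.p_value > 0.01

    def test_adjustment_reduces_confounding_bias(self):
        """With group confounded by age, ANCOVA beats the crude difference."""
        rng = np.random.default_rng(8)
        biases_crude, biases_adj = [], []
        for _ in range(50):
            n = 200
            age = rng.normal(65, 8, n)
            p_group = 1 / (1 + np.exp(-(age - 65) / 4))
            g = np.where(rng.random(n) < p_group, "severe", "mild")
            true_diff = 1.0
            y = true_diff * (g == "severe") + 0.3 * age + rng.normal(0, 1, n)
            crude = y[g == "severe"].mean() - y[g == "mild"].mean()
            adj = adjusted_group_difference(y, g, pd.DataFrame({"age": age}))
            biases_crude.append(abs(crude - true_diff))
            biases_adj.append(abs(adj.mean_difference - true_diff))
        assert np.mean(biases_adj) < np.mean(biases_crude)

    def test_rank_deficiency_rejected(self):
        g = np.repeat(["a", "b"], 10)
        cov = pd.DataFrame({"dup": (g == "b").astype(float)})
        with pytest.raises(ValueError, match="rank"):
            adjusted_group_difference(np.arange(20.0), g, cov)


class TestStandardizedRegression:
    def test_self_regression_beta_one(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=50)
        res = standardized_regression(x, pd.DataFrame({"x": x}))
        assert res.beta("x") == pytest.approx(1.0)
        assert res.table.loc["x", "ci_low"] > 0

    def test_negated_outcome_beta_minus_one(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=50)
        res = standardized_regression(-x, pd.DataFrame({"x": x}))
        assert res.beta("x") == pytest.approx(-1.0)

    def test_zero_variance_column_named(self):
        with pytest.raises(ValueError, match="flat"):
            standardized_regression(
                np.arange(10.0), pd.DataFrame({"flat": np.ones(10)})
            )

    def test_beta_recovery_simulation(self):
        """beta_true = 0.3 at n = 270: small bias, nominal CI coverage."""
        rng = np.random.default_rng(11)
        beta_true = 0.3
        noise_sd = np.sqrt(1 / beta_true**2 - 1) * beta_true  # R^2 ~ 0.09
        est, cover = [], 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(size=270)
            y = beta_true * x + rng.normal(0, np.sqrt(1 - beta_true**2), 270)
            res = standardized_regression(y, pd.DataFrame({"x": x}))
            est.append(res.beta("x"))
            lo, hi = res.table.loc["x", ["ci_low", "ci_high"]]
            cover += lo <= beta_true <= hi
        assert abs(np.mean(est) - beta_true) < 0.05
        assert 0.90 <= cover / reps <= 0.99


class TestMedianSplit:
    def test_even_split(self):
        labels = median_split(np.array([1.0, 2.0, 3.0, 4.0]))
        assert labels.tolist() == ["mild", "mild", "severe", "severe"]

    def test_ties_with_median_go_mild(self):
        labels = median_split(np.array([1.0, 2.0, 2.0, 9.0]))
        assert labels.tolist() == ["mild", "mild", "mild", "severe"]

    def test_all_identical_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            median_split(np.full(5, 3.3))

    def test_split_balance_up_to_ties(self):
        rng = np.random.default_rng(12)
        v = rng.lognormal(1, 1, 101)
        labels = median_split(v)
        n_tie = (v == np.median(v)).sum()
        assert abs((labels == "mild").sum() - (labels == "severe").sum()) <= n_tie


class TestLogTransform:
    def test_values(self):
        assert log_transform_wmh(1.0) == pytest.approx(0.0)
        assert log_transform_wmh(np.e) == pytest.approx(1.0)

    def test_monotone(self):
        rng = np.random.default_rng(13)
        v = np.sort(rng.lognormal(1, 1.3, 100))
        out = log_transform_wmh(v)
        assert np.all(np.diff(out) >= 0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            log_transform_wmh(np.array([1.0, 0.0]))


def _simulate_triple(rng, n, a, b, c_prime):
    x = rng.normal(size=n)
    m = a * x + rng.normal(size=n)
    y = b * m + c_prime * x + rng.normal(size=n)
    return x, m, y


class TestMediation:
    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(14)
        x, m, y = _simulate_triple(rng, 100, 0.5, 0.4, 0.1)
        r1 = fit_mediation(x, m, y, n_boot=500, seed=99)
        r2 = fit_mediation(x, m, y, n_boot=500, seed=99)
        assert r1 == r2

    def test_null_b_gives_null_indirect(self):
        rng = np.random.default_rng(15)
        n = 400
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n)
        y = 0.3 * x + rng.normal(size=n)  # y independent of m given x
        res = fit_mediation(x, m, y, n_boot=1000, seed=0)
        assert abs(res.indirect) < 0.1
        assert res.indirect_ci95[0] <= 0 <= res.indirect_ci95[1]

    def test_indirect_is_product_of_paths(self):
        rng = np.random.default_rng(16)
        x, m, y = _simulate_triple(rng, 200, 0.5, 0.4, 0.1)
        res = fit_mediation(x, m, y, n_boot=500, seed=1)
        assert res.indirect == pytest.approx(res.a * res.b)

    def test_total_effect_decomposition(self):
        """On standardized data: coefficient of y ~ x equals c' + a*b."""
        import statsmodels.api as sm

        rng = np.random.default_rng(17)
        x, m, y = _simulate_triple(rng, 300, 0.5, 0.4, 0.2)
        res = fit_mediation(x, m, y, n_boot=500, seed=2)
        xz = (x - x.mean()) / x.std(ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        total = sm.OLS(yz, sm.add_constant(xz)).fit().params[1]
        assert total == pytest.approx(res.c_prime + res.indirect, abs=1e-9)

    def test_matches_pingouin_paths(self):
        """Point estimates agree with pingouin's mediation analysis."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(18)
        x, m, y = _simulate_triple(rng, 250, 0.5, 0.4, 0.1)
        df = pd.DataFrame({
            "x": (x - x.mean()) / x.std(ddof=1),
            "m": (m - m.mean()) / m.std(ddof=1),
            "y": (y - y.mean()) / y.std(ddof=1),
        })
        res = fit_mediation(x, m, y, n_boot=500, seed=3)
        pg = pingouin.mediation_analysis(
            data=df, x="x", m="m", y="y", n_boot=500, seed=3
        ).set_index("path")
        assert res.indirect == pytest.approx(pg.loc["Indirect", "coef"], abs=1e-6)
        assert res.c_prime == pytest.approx(pg.loc["Direct", "coef"], abs=1e-6)

    def test_sobel_sign_matches_point_estimate(self):
        rng = np.random.default_rng(19)
        for a, b in [(0.5, 0.4), (-0.5, 0.4), (0.3, -0.6)]:
            x, m, y = _simulate_triple(rng, 2000, a, b, 0.1)
            res = fit_mediation(x, m, y, n_boot=500, seed=4)
            assert np.sign(res.sobel_z) == np.sign(res.indirect)
            # strong effect at n=2000: bootstrap and Sobel agree on significance
            boot_sig = not (res.indirect_ci95[0] <= 0 <= res.indirect_ci95[1])
            assert boot_sig == (res.sobel_p < 0.05)

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError, match="30"):
            fit_mediation(np.ones(10), np.ones(10), np.ones(10))

    def test_probit_option_for_binary_outcome(self):
        rng = np.random.default_rng(20)
        n = 400
        x = rng.normal(size=n)
        m = 0.6 * x + rng.normal(size=n)
        y = (rng.random(n) < sps.norm.cdf(-1.0 + 0.8 * m)).astype(float)
        res = fit_mediation(x, m, y, y_binary=True, y_model="probit",
                            n_boot=500, seed=5)
        assert res.b > 0
        assert res.b_p < 0.05
        with pytest.raises(ValueError, match="probit"):
            fit_mediation(x, m, y, y_model="probit")
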