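"""Survival core: KM, log-rank, Cox PH, AIC selection, ANOVA.

Oracles: hand product-limit calculations, an independent per-event-time
log-rank accumulation loop, a log-partial-likelihood grid scan, the
classical score-test/log-rank equivalence, and lifelines as an external
cross-check implementation.
"""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter

from pcnsl_immune import (
    aic_select,
    compare_groups,
    cox_fit,
    cox_score_test,
    km_estimate,
    logrank_test,
    one_way_anova,
)
from pcnsl_immune.exceptions import ValidationError
from pcnsl_immune.survival import all_subsets


def brute_force_logrank_2group(times, events, groups):
    """Independent O-E / hypergeometric-variance accumulation, two groups."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    lab = np.unique(groups)[0]
    o_minus_e = 0.0
    var = 0.0
    for et in np.unique(times[events == 1]):
        at_risk = times >= et
        n = at_risk.sum()
        n1 = (at_risk & (groups == lab)).sum()
        d = ((times == et) & (events == 1)).sum()
        d1 = ((times == et) & (events == 1) & (groups == lab)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # risk set 3 at t=8 with 2 events -> S=1/3; risk set 1 at t=12 -> 0
        curve = km_estimate([5, 8, 8, 12], [0, 1, 1, 1])
        np.testing.assert_array_equal(curve.times, [8, 12])
        np.testing.assert_allclose(curve.survival, [1 / 3, 0.0])
        assert curve.survival_at(7.9) == 1.0

    def test_all_censored_is_flat_one(self):
        curve = km_estimate([3, 5, 9], [0, 0, 0])
        assert curve.times.size == 0
        assert curve.survival_at(100.0) == 1.0

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, size=80)
        curve = km_estimate(t, np.ones(80, int))
        for et in curve.times:
            ecdf = np.mean(t <= et)
            assert curve.survival_at(et) == pytest.approx(1 - ecdf, abs=1e-12)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(2)
        t = np.ceil(rng.exponential(10, size=60))
        e = (rng.uniform(size=60) < 0.7).astype(int)
        curve = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ref = kmf.survival_function_at_times(curve.times).to_numpy()
        np.testing.assert_allclose(curve.survival, ref, atol=1e-12)

    def test_empty_input_error(self):
        with pytest.raises(ValidationError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [3, 5, 7, 9, 3, 5, 7, 9]
        e = [1, 1, 0, 1, 1, 1, 0, 1]
        g = ["a"] * 4 + ["b"] * 4
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_toy_data_significant(self):
        res = logrank_test([1, 2, 3, 10, 20, 30], [1] * 6, list("aaabbb"))
        assert res.statistic > 3.84  # p < 0.05 at 1 df

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(5, 40)
        e = (rng.uniform(size=40) < 0.8).astype(int)
        g = rng.choice(["x", "y"], 40)
        flipped = np.where(g == "x", "y", "x")
        assert logrank_test(t, e, g).statistic == pytest.approx(
            logrank_test(t, e, flipped).statistic, rel=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_oracle_two_groups(self, seed):
        rng = np.random.default_rng(seed)
        t = np.ceil(rng.exponential(5, 50))
        e = (rng.uniform(size=50) < 0.75).astype(int)
        g = rng.choice(["a", "b"], 50)
        expected = brute_force_logrank_2group(t, e, g)
        assert logrank_test(t, e, g).statistic == pytest.approx(expected, abs=1e-10)

    def test_three_group_df(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(5, 60)
        e = np.ones(60, int)
        g = rng.choice(list("abc"), 60)
        res = logrank_test(t, e, g)
        assert res.df == 2

    def test_single_group_error(self):
        with pytest.raises(ValidationError):
            logrank_test([1, 2], [1, 1], ["a", "a"])


class TestCox:
    def test_parameter_recovery_binary_covariate(self):
        rng = np.random.default_rng(10)
        n = 500
        g = (rng.uniform(size=n) < 0.5).astype(float)
        t = rng.exponential(1 / (0.01 * 2.0**g))
        e = np.ones(n, int)
        fit = cox_fit(g[:, None], t, e)
        assert 1.6 <= fit.hr[0] <= 2.5
        assert fit.ci_low[0] < 2.0 < fit.ci_high[0]

    def test_constant_covariate_error(self):
        with pytest.raises(ValidationError, match="constant"):
            cox_fit(np.zeros((10, 1)), np.arange(1, 11), np.ones(10, int))

    def test_partial_likelihood_maximized_on_grid(self):
        from pcnsl_immune.survival import _cox_quantities

        rng = np.random.default_rng(11)
        n = 20
        x = rng.standard_normal((n, 1))
        t = rng.exponential(1 / np.exp(0.5 * x[:, 0]))
        e = np.ones(n, int)
        fit = cox_fit(x, t, e)
        xc = x - x.mean(axis=0)
        ll_hat = fit.log_likelihood
        for beta in np.linspace(fit.coef[0] - 2, fit.coef[0] + 2, 81):
            ll, _, _ = _cox_quantities(np.array([beta]), xc, t, e, "efron")
            assert ll <= ll_hat + 1e-9

    def test_matches_lifelines_efron(self):
        rng = np.random.default_rng(12)
        n = 150
        x = rng.standard_normal((n, 2))
        t = np.ceil(rng.exponential(1 / (0.01 * np.exp(0.6 * x[:, 0]))))
        e = (rng.uniform(size=n) < 0.8).astype(int)
        fit = cox_fit(x, t, e, ties="efron")
        df = pd.DataFrame({"t": t, "e": e, "x0": x[:, 0], "x1": x[:, 1]})
        ref = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(fit.coef, ref.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(fit.se, ref.standard_errors_.to_numpy(), atol=1e-5)
        assert fit.log_likelihood == pytest.approx(ref.log_likelihood_, abs=1e-6)

    def test_breslow_equals_efron_without_ties(self):
        # the two tie corrections coincide on tie-free data
        rng = np.random.default_rng(15)
        n = 100
        x = rng.standard_normal((n, 2))
        t = rng.exponential(1 / np.exp(0.4 * x[:, 0]))
        e = (rng.uniform(size=n) < 0.85).astype(int)
        f1 = cox_fit(x, t, e, ties="efron")
        f2 = cox_fit(x, t, e, ties="breslow")
        np.testing.assert_allclose(f1.coef, f2.coef, atol=1e-8)
        assert f1.log_likelihood == pytest.approx(f2.log_likelihood, abs=1e-8)

    def test_score_test_equals_logrank_tie_free(self):
        rng = np.random.default_rng(13)
        n = 60
        t = rng.exponential(5, n)  # continuous -> tie-free
        e = np.ones(n, int)
        g = (rng.uniform(size=n) < 0.5).astype(float)
        stat, _ = cox_score_test(g, t, e)
        lr = logrank_test(t, e, g)
        assert stat == pytest.approx(lr.statistic, abs=1e-6)

    def test_aic_identity(self):
        assert_fit = lambda f: f.aic == pytest.approx(2 * len(f.covariates) - 2 * f.log_likelihood)
        rng = np.random.default_rng(14)
        x = rng.standard_normal((80, 2))
        t = rng.exponential(1 / np.exp(0.5 * x[:, 0]))
        e = np.ones(80, int)
        full = cox_fit(x, t, e)
        reduced = cox_fit(x[:, :1], t, e)
        assert_fit(full)
        assert_fit(reduced)
        # nested-model identity
        assert full.aic == pytest.approx(
            reduced.aic + 2 - 2 * (full.log_likelihood - reduced.log_likelihood)
        )


class TestAicSelect:
    def _sim(self, seed, n=300):
        rng = np.random.default_rng(seed)
        inf = rng.standard_normal(n)
        noise = rng.standard_normal(n)
        t = rng.exponential(1 / (0.01 * np.exp(0.8 * inf)))
        e = (rng.uniform(size=n) < 0.85).astype(int)
        return pd.DataFrame({"informative": inf, "noise": noise}), t, e

    def test_noise_covariate_usually_excluded(self):
        # min-AIC admits a pure-noise covariate with asymptotic probability
        # P(chi2_1 > 2) ~ 0.157, so the exclusion rate is calibrated near 84%
        hits = 0
        reps = 100
        for seed in range(reps):
            cov, t, e = self._sim(seed)
            subset, _ = aic_select(all_subsets(["informative", "noise"]), cov, t, e)
            hits += subset == ("informative",)
        assert hits >= 75
        # the informative covariate itself is never dropped
        assert hits <= reps

    def test_single_candidate_returned(self):
        cov, t, e = self._sim(0)
        subset, fit = aic_select([("noise",)], cov, t, e)
        assert subset == ("noise",)
        assert fit.covariates == ["noise"]

    def test_all_failing_raises(self):
        cov = pd.DataFrame({"flat": np.zeros(10)})
        with pytest.warns(UserWarning):
            with pytest.raises(ValidationError):
                aic_select([("flat",)], cov, np.arange(1, 11), np.ones(10, int))


class TestAnova:
    def test_identical_groups(self):
        f, df1, df2, p = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert (df1, df2) == (1, 4)
        assert p == pytest.approx(1.0)

    def test_separated_groups(self):
        rng = np.random.default_rng(5)
        g1 = rng.normal(0, 1e-9, 3)
        g2 = 10 + rng.normal(0, 1e-9, 3)
        _, _, _, p = one_way_anova([g1, g2])
        assert p < 1e-6

    def test_degenerate_equal_constants(self):
        f, _, _, p = one_way_anova([[5, 5], [5, 5]])
        assert (f, p) == (0.0, 1.0)

    def test_sums_of_squares_oracle(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(m, 1, size=n) for m, n in [(0, 8), (1, 5), (0.5, 7), (2, 6)]]
        f, df1, df2, p = one_way_anova(groups)
        grand = np.concatenate(groups).mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_oracle = (ssb / df1) / (ssw / df2)
        assert f == pytest.approx(f_oracle, abs=1e-10)

    def test_too_few_groups(self):
        with pytest.raises(ValidationError):
            one_way_anova([[1, 2, 3]])


class TestCompareGroups:
    def test_two_group_hr_direction(self):
        rng = np.random.default_rng(20)
        n = 200
        g = np.where(rng.uniform(size=n) < 0.5, "high", "low")
        rate = np.where(g == "high", 0.02, 0.01)
        t = rng.exponential(1 / rate)
        comp = compare_groups(t, np.ones(n, int), g, reference="low")
        assert comp.hr > 1
        assert comp.ci95[0] < comp.hr < comp.ci95[1]
        assert set(comp.curves) == {"high", "low"}

    def test_bad_reference(self):
        with pytest.raises(ValidationError):
            compare_groups([1, 2], [1, 1], ["a", "b"], reference="zzz")
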