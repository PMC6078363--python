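"""Logistic fitting, quantile odds ratios, forward selection,
calibration and collinearity — each checked against an independent
route (closed forms, generic optimizer, statsmodels, brute force)."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from cadgrs import (SimConfig, collinearity, contingency_2x2, fit_logistic,
                    forward_wald_selection, hosmer_lemeshow, quantile_assign,
                    quartile_or, simulate_cohort)
from cadgrs.panel import SnpPanel, SnpSpec


def _data_from_2x2(a, b, c, d):
    """Subjects for a 2x2 (rows: exposed/unexposed, cols: case/control)."""
    x = np.repeat([1.0, 1.0, 0.0, 0.0], [a, b, c, d])
    y = np.repeat([1.0, 0.0, 1.0, 0.0], [a, b, c, d])
    return x, y


class TestFitLogistic:
    def test_saturated_2x2_matches_cross_product_or(self):
        # (30, 20, 10, 40): OR = 30*40 / (20*10) = 6
        x, y = _data_from_2x2(30, 20, 10, 40)
        fit = fit_logistic(x[:, None], y)
        assert fit.converged
        assert fit.params[1] == pytest.approx(np.log(6.0), abs=1e-8)
        ct = contingency_2x2([[30, 20], [10, 40]])
        assert ct.odds_ratio == pytest.approx(6.0)

    def test_null_data_gives_null_or(self, rng):
        x = rng.standard_normal((4000, 2))
        y = rng.integers(0, 2, 4000).astype(float)
        fit = fit_logistic(pd.DataFrame(x, columns=["a", "b"]), y)
        ci = fit.conf_int()
        for j in (1, 2):
            assert ci[j, 0] <= 1.0 <= ci[j, 1]
            assert abs(fit.zvalues[j]) < 4.0

    def test_loglik_matches_generic_optimizer(self, rng):
        # oracle: direct likelihood maximisation with scipy
        X = rng.standard_normal((200, 3))
        beta_true = np.array([-0.5, 0.8, -0.3, 0.2])
        Xd = np.column_stack([np.ones(200), X])
        y = (rng.random(200) < expit(Xd @ beta_true)).astype(float)

        def negll(b):
            mu = expit(Xd @ b)
            return -np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))

        opt = minimize(negll, np.zeros(4), method="BFGS")
        fit = fit_logistic(X, y)
        assert fit.llf == pytest.approx(-opt.fun, abs=1e-4)
        np.testing.assert_allclose(fit.params, opt.x, atol=1e-3)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        X = rng.standard_normal((300, 2))
        y = (rng.random(300) < expit(0.3 + X @ [0.7, -0.4])).astype(float)
        fit = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(fit.params, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.bse, ref.bse, rtol=1e-4)

    def test_complete_separation_flagged(self):
        x = np.linspace(-2, 2, 60)
        y = (x > 0).astype(float)
        fit = fit_logistic(x[:, None], y)
        assert not fit.converged
        assert fit.diverging

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.standard_normal(100)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="b"):
            fit_logistic(X, (x > 0).astype(float))

    def test_nonbinary_outcome_rejected(self, rng):
        with pytest.raises(ValueError, match="binary"):
            fit_logistic(rng.standard_normal((10, 1)), np.arange(10))


class TestQuartileOr:
    def test_risk_gradient_with_true_effects(self, fitted_results):
        tab = fitted_results.quartile_or_unadjusted.table
        ors = tab["or"].to_numpy()
        assert ors[0] == 1.0
        assert ors[1] > 1.0 and ors[2] > ors[1] and ors[3] > ors[2]
        # matches direct 2x2 ORs per bin (oracle)
        res = fitted_results
        bins = res.quartiles.bins.to_numpy()
        y = res.model.cohort.phenotype.to_numpy()
        for b in (2, 3, 4):
            a = ((bins == b) & (y == 1)).sum()
            bb = ((bins == b) & (y == 0)).sum()
            c = ((bins == 1) & (y == 1)).sum()
            d = ((bins == 1) & (y == 0)).sum()
            direct = (a * d) / (bb * c)
            assert tab.loc[tab.bin == b, "or"].iloc[0] == pytest.approx(
                direct, rel=1e-6)

    def test_binary_split_equals_single_fit(self, fitted_results):
        res = fitted_results
        scores = res.multiplicative.scores
        y = res.model.cohort.phenotype.to_numpy()
        qa = quantile_assign(scores, 2)
        two = quartile_or(res.model.cohort, qa)
        x = (qa.bins.to_numpy() == 2).astype(float)
        single = fit_logistic(x[:, None], y)
        assert two.table.loc[1, "or"] == pytest.approx(
            np.exp(single.params[1]), rel=1e-8)

    def test_null_bin_or_ci_coverage(self):
        # noise score: per-bin Wald CIs cover OR = 1 at ~95% in the
        # asymptotic regime (400 per group keeps bins at ~200 subjects)
        panel = SnpPanel([SnpSpec("s", maf=0.3, per_allele_or=1.0)])
        covered = total = 0
        for seed in range(20):
            cohort = simulate_cohort(SimConfig(n_cases=400, n_controls=400,
                                               seed=seed,
                                               population_multiplier=8.0),
                                     panel)
            rng = np.random.default_rng(seed + 1000)
            scores = pd.Series(rng.standard_normal(cohort.n_subjects),
                               index=cohort.genotypes.index)
            qa = quantile_assign(scores, 4)
            tab = quartile_or(cohort, qa).table
            for b in (2, 3, 4):
                row = tab[tab.bin == b].iloc[0]
                covered += row.ci_low <= 1.0 <= row.ci_high
                total += 1
        assert covered / total >= 0.90

    def test_reference_bin_is_unity(self, fitted_results):
        row = fitted_results.quartile_or_adjusted.table.iloc[0]
        assert (row["or"], row.ci_low, row.ci_high) == (1.0, 1.0, 1.0)

    def test_unknown_preset_rejected(self, fitted_results):
        res = fitted_results
        with pytest.raises(KeyError, match="preset"):
            quartile_or(res.model.cohort, res.quartiles, adjust="nope")


class TestForwardSelection:
    def test_true_predictor_enters_first(self, rng):
        n = 3000
        X = pd.DataFrame(rng.standard_normal((n, 6)),
                         columns=[f"x{j}" for j in range(6)])
        y = (rng.random(n) < expit(-1 + np.log(2.0) * X["x3"])).astype(float)
        res = forward_wald_selection(X, y)
        assert res.selected[0] == "x3"
        # oracle: exhaustive single-variable fits agree on the winner
        single_p = {c: fit_logistic(X[[c]], y).pvalues[-1] for c in X}
        assert min(single_p, key=single_p.get) == "x3"

    def test_all_noise_rarely_selects(self):
        empty = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.standard_normal((300, 4)),
                             columns=list("abcd"))
            y = r.integers(0, 2, 300).astype(float)
            res = forward_wald_selection(X, y)
            empty += not res.selected
        assert empty >= 6  # ~81% expected with 4 candidates at p < 0.05

    def test_entry_p_one_admits_everything(self, rng):
        X = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("abc"))
        y = rng.integers(0, 2, 200).astype(float)
        res = forward_wald_selection(X, y, entry_p=1.0)
        assert sorted(res.selected) == ["a", "b", "c"]
        # inclusion order follows Wald p at each step
        assert res.trace[0]["entered"] == min(
            res.trace[0]["candidate_p"], key=res.trace[0]["candidate_p"].get)


class TestHosmerLemeshow:
    def test_calibrated_probabilities_statistic_distribution(self):
        # oracle: simulate outcomes from stated (external, unfitted)
        # risks; the statistic is then ~chi2 on g df (the g-2 convention
        # applies to in-sample fitted probabilities), so tail
        # probabilities on g df should be uniform over replicates
        from scipy.stats import chi2 as chi2_dist
        from scipy.stats import kstest

        rng = np.random.default_rng(21)
        probs = rng.beta(2, 5, size=2000)
        tail = []
        for _ in range(200):
            res = hosmer_lemeshow(probs,
                                  (rng.random(2000) < probs).astype(float))
            tail.append(float(chi2_dist.sf(res.statistic, res.n_groups)))
        assert kstest(tail, "uniform").pvalue > 0.01

    def test_gross_miscalibration_detected(self):
        rng = np.random.default_rng(22)
        probs = rng.beta(2, 3, size=3000)
        y = (rng.random(3000) < probs).astype(float)
        res = hosmer_lemeshow(probs ** 2, y)
        assert res.p_value < 1e-6

    def test_minimal_three_groups(self, rng):
        probs = rng.random(60)
        y = (rng.random(60) < probs).astype(float)
        res = hosmer_lemeshow(probs, y, groups=3)
        assert res.df == 1 and np.isfinite(res.statistic)

    def test_too_few_groups_rejected(self, rng):
        with pytest.raises(ValueError):
            hosmer_lemeshow(rng.random(50), np.zeros(50), groups=2)


class TestCollinearity:
    def test_orthogonal_predictors_unit_vif(self):
        n = 64
        X = pd.DataFrame({"a": np.tile([1.0, -1.0], n // 2),
                          "b": np.repeat([1.0, -1.0], n // 2)})
        rep = collinearity(X)
        np.testing.assert_allclose(rep.table.vif, 1.0, atol=1e-10)

    def test_duplicate_column_infinite_vif(self, rng):
        x = rng.standard_normal(100)
        rep = collinearity(pd.DataFrame({"a": x, "b": x}))
        assert rep.table.perfectly_collinear.all()
        assert np.isinf(rep.table.vif).all()

    def test_bivariate_closed_form(self, rng):
        # r = 0.9 exactly by construction -> VIF = 1/(1-0.81)
        n = 5000
        x1 = rng.standard_normal(n)
        e = rng.standard_normal(n)
        x1c = (x1 - x1.mean()) / x1.std()
        ec = e - e.mean()
        ec -= x1c * (ec @ x1c) / (x1c @ x1c)  # orthogonalise
        ec /= ec.std()
        x2 = 0.9 * x1c + np.sqrt(1 - 0.81) * ec
        rep = collinearity(pd.DataFrame({"a": x1c, "b": x2}))
        np.testing.assert_allclose(rep.table.vif, 1.0 / (1.0 - 0.81),
                                   rtol=1e-10)

    def test_study_style_model_not_collinear(self, fitted_results):
        assert fitted_results.collinearity.max_vif() < 10.0
        assert (fitted_results.collinearity.table.tolerance > 0.1).all()


class TestContingency:
    def test_fisher_selected_for_sparse_table(self):
        res = contingency_2x2([[2, 10], [1, 30]])
        assert res.test == "fisher"

    def test_chi2_for_dense_table(self):
        res = contingency_2x2([[30, 20], [10, 40]])
        assert res.test == "chi2"
        assert res.ci[0] < res.odds_ratio < res.ci[1]
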