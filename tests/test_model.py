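"""Logistic fitting, DeLong AUC machinery, patterns, tetrachorics —
each checked against an independent closed form, brute force, or
simulation oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit
from scipy.stats import norm

import misutil as mu
from misutil.ingest import DesignMatrix


def _design(df: pd.DataFrame, covariate_set: str = "c") -> DesignMatrix:
    return DesignMatrix(data=df.astype(float), covariate_set=covariate_set)


def auc_pair_oracle(scores, y):
    """O(n^2) pair counting: P(score_event > score_nonevent) + 1/2 ties."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 30 + [0] * 70)
        design = _design(pd.DataFrame({"intercept": np.ones(100)}))
        fit = mu.fit_logistic(design, y)
        assert fit.coefficients["intercept"] == pytest.approx(float(logit(0.3)), abs=1e-8)
        assert fit.converged
        assert np.all((fit.fitted_probabilities > 0) & (fit.fitted_probabilities < 1))

    def test_two_by_two_slope_is_log_odds_ratio(self):
        # group x=0: 20/100 events; x=1: 50/100 -> slope = log[(50*80)/(50*20)]
        x = np.repeat([0, 1], 100)
        y = np.concatenate([[1] * 20 + [0] * 80, [1] * 50 + [0] * 50])
        design = _design(pd.DataFrame({"intercept": np.ones(200), "x": x}))
        fit = mu.fit_logistic(design, y)
        assert fit.coefficients["x"] == pytest.approx(np.log(50 * 80 / (50 * 20)), abs=1e-8)
        # Wald SE of a 2x2 log-OR has a closed form too
        se = np.sqrt(1 / 50 + 1 / 50 + 1 / 20 + 1 / 80)
        assert fit.standard_errors["x"] == pytest.approx(se, abs=1e-6)

    def test_single_class_rejected(self):
        design = _design(pd.DataFrame({"intercept": np.ones(10)}))
        with pytest.raises(ValueError):
            mu.fit_logistic(design, np.ones(10))

    def test_separation_warns(self):
        x = np.repeat([0.0, 1.0], 20)
        y = np.repeat([0, 1], 20)  # perfect separation
        design = _design(pd.DataFrame({"intercept": np.ones(40), "x": x}))
        with pytest.warns(mu.SeparationWarning):
            mu.fit_logistic(design, y)

    def test_recovers_generator_truth(self, fitted50k):
        cohort, cfg, fit, y = fitted50k
        cols = [c for c in fit.coefficients if c != "intercept"]
        truth = {c: cfg.true_coefficients.get(c, 0.0) for c in cols}
        truth["intercept"] = cfg.true_intercept
        outside = sum(
            abs(fit.coefficients[c] - truth.get(c, 0.0)) > 3 * fit.standard_errors[c]
            for c in fit.coefficients
        )
        assert outside / len(fit.coefficients) <= 0.05

    def test_nesting_of_log_likelihoods(self, fits50k):
        _, _, fits, _ = fits50k
        ll = {cs: fits[cs].log_likelihood for cs in ("a", "b", "c")}
        assert ll["a"] >= max(ll["b"], ll["c"]) - 1e-6

    def test_score_equations_satisfied(self, small_cohort):
        design = mu.build_design(small_cohort, "c")
        y = small_cohort["outcome_used"].to_numpy()
        fit = mu.fit_logistic(design, y)
        X = design.to_numpy()
        grad = X.T @ (y - fit.fitted_probabilities)
        assert np.abs(grad).max() < 1e-6


class TestAucDelong:
    def test_perfect_separation_gives_one(self):
        est = mu.auc_delong([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert est.auc == 1.0

    def test_one_swapped_pair_gives_three_quarters(self):
        # events {0.9, 0.2}, non-events {0.1, 0.8}: one discordant pair of four
        est = mu.auc_delong([0.9, 0.2, 0.8, 0.1], [1, 1, 0, 0])
        assert est.auc == pytest.approx(0.75)
        assert est.ci95[0] <= est.auc <= est.ci95[1]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_pair_counting_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        scores = rng.integers(0, 20, size=n) / 20.0  # discrete -> many ties
        y = rng.integers(0, 2, size=n)
        y[:2] = [0, 1]  # both classes present
        est = mu.auc_delong(scores, y)
        assert est.auc == pytest.approx(auc_pair_oracle(scores, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mu.auc_delong([0.5, 0.6], [1, 1])

    def test_ci_truncated_to_unit_interval(self):
        est = mu.auc_delong([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert 0.0 <= est.ci95[0] <= est.ci95[1] <= 1.0


class TestCompareAuc:
    def test_identical_scores_give_zero_diff_p_one(self):
        p = np.linspace(0.1, 0.9, 50)
        y = (np.arange(50) % 2).astype(int)
        diff, ci, pval = mu.compare_auc_delong(p, p, y)
        assert diff == 0.0
        assert pval == 1.0

    def test_antisymmetric_in_arguments(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 300)
        y[:2] = [0, 1]
        pa = np.clip(0.3 * y + rng.random(300) * 0.6, 0.01, 0.99)
        pb = rng.random(300)
        d1, ci1, p1 = mu.compare_auc_delong(pa, pb, y)
        d2, ci2, p2 = mu.compare_auc_delong(pb, pa, y)
        assert d1 == pytest.approx(-d2)
        assert p1 == pytest.approx(p2)
        assert ci1[0] == pytest.approx(-ci2[1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mu.compare_auc_delong([0.1, 0.2], [0.1], [1, 0])

    def test_variance_against_paired_bootstrap(self):
        rng = np.random.default_rng(17)
        n = 500
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        signal = 0.8 * y + rng.standard_normal(n)
        pa = 1 / (1 + np.exp(-(signal + 0.5 * rng.standard_normal(n))))
        pb = 1 / (1 + np.exp(-(signal + 1.5 * rng.standard_normal(n))))
        _, _, _ = mu.compare_auc_delong(pa, pb, y)
        aucs, v10, v01 = mu.model._delong_components(np.vstack([pa, pb]), y)
        S = mu.model._delong_cov(v10, v01)
        var_delong = S[0, 0] + S[1, 1] - 2 * S[0, 1]
        diffs = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            while y[idx].min() == y[idx].max():
                idx = rng.integers(0, n, n)
            a, _, _ = mu.model._delong_components(np.vstack([pa[idx], pb[idx]]), y[idx])
            diffs.append(a[0] - a[1])
        var_boot = np.var(diffs, ddof=1)
        assert var_delong == pytest.approx(var_boot, rel=0.15)


class TestPatterns:
    def test_hand_computed_chi_square(self, make_hand_cohort):
        visits = (
            [("0000000", 1)] * 5 + [("0000000", 0)] * 5
            + [("1000000", 1)] * 2 + [("1000000", 0)] * 18
            + [("0000001", 1)] * 1 + [("0000001", 0)] * 9
        )
        summaries, stat, dof, p = mu.pattern_analysis(make_hand_cohort(visits))
        assert stat == pytest.approx(7.5, abs=1e-10)  # sum (O-E)^2/E by hand
        assert dof == 2
        assert sum(s.count for s in summaries) == 40

    def test_identical_rates_give_zero_statistic(self, make_hand_cohort):
        visits = ([("0000000", 1), ("0000000", 0), ("1111111", 1), ("1111111", 0)])
        _, stat, dof, p = mu.pattern_analysis(make_hand_cohort(visits))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_invariant_to_resource_permutation(self, small_cohort):
        _, stat, dof, _ = mu.pattern_analysis(small_cohort)
        permuted = small_cohort.copy()
        a, b = mu.RESOURCES[0], mu.RESOURCES[-1]
        permuted[a], permuted[b] = small_cohort[b].copy(), small_cohort[a].copy()
        _, stat2, dof2, _ = mu.pattern_analysis(permuted)
        assert stat == pytest.approx(stat2)
        assert dof == dof2

    def test_needs_two_patterns(self, make_hand_cohort):
        with pytest.raises(ValueError):
            mu.pattern_analysis(make_hand_cohort([("0000000", 1), ("0000000", 0)]))


class TestTetrachoric:
    def test_independence_table(self):
        rho = mu.tetrachoric_rho(np.array([[25, 25], [25, 25]]))
        assert abs(rho) < 1e-3

    def test_perfect_concordance_hits_bound(self):
        rho = mu.tetrachoric_rho(np.array([[50, 0], [0, 50]]))
        assert rho >= 0.99

    def test_empty_margin_flagged_undefined(self):
        assert np.isnan(mu.tetrachoric_rho(np.array([[30, 10], [0, 0]])))

    def test_recovers_latent_correlation(self):
        # copula simulation oracle: threshold a bivariate normal with rho=0.5
        rng = np.random.default_rng(23)
        n = 100000
        rho = 0.5
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        x = (z1 > norm.ppf(1 - 0.3)).astype(int)
        y = (z2 > norm.ppf(1 - 0.6)).astype(int)
        table = np.array([[np.sum((x == i) & (y == j)) for j in (0, 1)] for i in (0, 1)])
        assert mu.tetrachoric_rho(table) == pytest.approx(0.5, abs=0.03)

    def test_full_pair_list(self, small_cohort):
        ests = mu.tetrachoric(small_cohort)
        assert len(ests) == 21 + 7
        assert all(abs(e.rho) <= 1 for e in ests if e.defined)
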