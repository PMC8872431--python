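"""Facility aggregation, exact Poisson tail tests, flagging, rankings,
volume regressions."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import misutil as mu


def _profiles(counts_volumes):
    ids = [f"F{i:03d}" for i in range(len(counts_volumes))]
    mis = [c for c, v in counts_volumes]
    vol = [v for c, v in counts_volumes]
    return mu.profiles_from_counts(ids, vol, mis_count=mis)


class TestFacilityRates:
    def test_hand_fixture_rates(self):
        # 30 visits: 9 over + 5 under = 14 mis -> 46.67% / 30.00% / 16.67%
        labels = np.array(["over"] * 9 + ["under"] * 5 + ["concordant_unused"] * 16)
        cohort = pd.DataFrame({"facility_id": ["F1221"] * 30})
        prof = mu.facility_rates(labels, cohort).iloc[0]
        assert round(100 * prof["mis_rate"], 2) == 46.67
        assert round(100 * prof["over_rate"], 2) == 30.00
        assert round(100 * prof["under_rate"], 2) == 16.67

    def test_zero_mislabeled_facility(self):
        labels = np.array(["concordant_used"] * 40)
        prof = mu.facility_rates(labels, pd.DataFrame({"facility_id": ["F0"] * 40}))
        assert prof.iloc[0][["mis_rate", "over_rate", "under_rate"]].eq(0).all()

    def test_rates_decompose(self, fitted50k):
        cohort, _, fit, y = fitted50k
        labels, _ = mu.classify_visits(fit.fitted_probabilities, y, 0.2)
        prof = mu.facility_rates(labels, cohort)
        assert np.allclose(prof["mis_rate"], prof["over_rate"] + prof["under_rate"])
        assert prof["mis_count"].sum() == np.isin(labels, ["over", "under"]).sum()
        assert prof["volume"].sum() == len(cohort)


class TestPooledRate:
    def test_equal_rates(self):
        prof = _profiles([(2, 10), (4, 20), (8, 40)])
        assert mu.pooled_rate(prof, "mis") == pytest.approx(0.2)

    def test_two_facility_arithmetic(self):
        prof = _profiles([(2, 10), (8, 40)])
        assert mu.pooled_rate(prof, "mis") == pytest.approx(0.2)

    def test_matches_offset_poisson_glm(self):
        # pooled rate equals exp(intercept) of a log-link Poisson fit with
        # offset ln(volume)
        rng = np.random.default_rng(4)
        vol = rng.integers(5, 300, 50)
        counts = rng.poisson(0.17 * vol)
        prof = mu.profiles_from_counts([f"F{i}" for i in range(50)], vol, mis_count=counts)
        glm = sm.GLM(counts, np.ones((50, 1)), family=sm.families.Poisson(),
                     offset=np.log(vol)).fit()
        assert mu.pooled_rate(prof, "mis") == pytest.approx(
            float(np.exp(glm.params[0])), abs=1e-8)

    def test_zero_volume_rejected(self):
        prof = _profiles([(0, 0)])
        prof["volume"] = 0
        with pytest.raises(ValueError):
            mu.pooled_rate(prof, "mis")


class TestPoissonTail:
    def test_zero_count_gives_one(self):
        assert mu.poisson_upper_p(0, 3.7) == 1.0

    def test_matches_pmf_summation(self):
        for c, mean in [(10, 5.0), (3, 12.5), (25, 25.0), (49, 50.0)]:
            brute = sum(stats.poisson.pmf(k, mean) for k in range(c, c + 400))
            assert mu.poisson_upper_p(c, mean) == pytest.approx(brute, abs=1e-10)

    def test_decreasing_in_count(self):
        ps = [mu.poisson_upper_p(c, 8.0) for c in range(0, 30)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_negative_or_fractional_rejected(self):
        with pytest.raises(ValueError):
            mu.poisson_upper_p(-1, 2.0)
        with pytest.raises(ValueError):
            mu.poisson_upper_p(2.5, 2.0)


class TestFlagging:
    def test_null_facilities_not_flagged_at_small_volume(self):
        prof = _profiles([(2, 10)] * 30)  # everyone exactly at the pooled rate
        flagged = mu.flag_facilities(prof, alpha=0.01)
        assert all(len(flagged[k]) == 0 for k in ("mis",))

    def test_flag_monotone_in_volume(self):
        # 2x the pooled rate: detectable at volume 400, not at volume 20
        background = [(10, 100)] * 50
        prof_small = _profiles(background + [(4, 20)])
        prof_big = _profiles(background + [(80, 400)])
        assert "F050" not in set(mu.flag_facilities(prof_small)["mis"]["facility_id"])
        assert "F050" in set(mu.flag_facilities(prof_big)["mis"]["facility_id"])

    def test_ranking_deterministic(self):
        prof = _profiles([(30, 100), (40, 100), (5, 100), (5, 100), (6, 120)])
        flagged = mu.flag_facilities(prof, alpha=0.5)["mis"]
        ps = flagged["mis_p"].to_numpy()
        assert (np.diff(ps) >= 0).all()

    def test_planted_outlier_recovery_and_null_calibration(self):
        # 10 facilities at 3x the base rate among 1000 nulls: high sensitivity,
        # null flag rate at or below twice alpha (exact tails are conservative)
        rng = np.random.default_rng(99)
        base = 0.17
        sens, null_rate = [], []
        for _ in range(10):
            vol = rng.integers(20, 300, 1000)
            out_vol = rng.integers(100, 300, 10)
            counts = rng.poisson(base * vol)
            out_counts = rng.poisson(3 * base * out_vol)
            prof = mu.profiles_from_counts(
                [f"N{i:04d}" for i in range(1000)] + [f"O{i:02d}" for i in range(10)],
                np.concatenate([vol, out_vol]),
                mis_count=np.concatenate([counts, out_counts]))
            flagged = set(mu.flag_facilities(prof, 0.01)["mis"]["facility_id"])
            sens.append(sum(f.startswith("O") for f in flagged) / 10)
            null_rate.append(sum(f.startswith("N") for f in flagged) / 1000)
        assert np.mean(sens) >= 0.8
        assert np.mean(null_rate) <= 0.02

    def test_bh_flags_subset_of_raw(self):
        rng = np.random.default_rng(12)
        vol = rng.integers(20, 200, 200)
        counts = rng.poisson(0.15 * vol)
        prof = mu.profiles_from_counts([f"F{i}" for i in range(200)], vol, mis_count=counts)
        raw = set(mu.flag_facilities(prof, 0.05)["mis"]["facility_id"])
        bh = set(mu.flag_facilities(prof, 0.05, method="bh")["mis"]["facility_id"])
        assert bh <= raw


class TestBubbleData:
    def test_empty_when_none_flagged(self):
        prof = _profiles([(2, 10)] * 20)
        assert len(mu.bubble_data(prof, "mis")) == 0

    def test_flagged_rows_exceed_expectation(self):
        prof = _profiles([(10, 100)] * 50 + [(60, 100)])
        bubbles = mu.bubble_data(prof, "mis")
        assert len(bubbles) >= 1
        assert (bubbles["actual"] > bubbles["expected"]).all()

    def test_expected_is_pooled_rate_times_volume(self):
        prof = _profiles([(10, 100)] * 5 + [(50, 100)])
        lam = mu.pooled_rate(prof, "mis")
        enriched = mu.add_expected_and_p(prof)
        assert np.allclose(enriched["mis_expected"], lam * enriched["volume"], atol=1e-10)


class TestVolumeRegression:
    def test_constant_rates_give_zero_slope(self):
        prof = _profiles([(10, 50), (20, 100), (40, 200), (80, 400)])
        reg = mu.volume_regression(prof, "mis")
        assert reg.slope == pytest.approx(0.0, abs=1e-10)

    def test_three_point_hand_ols(self):
        # x = ln(v), y = rate% ; normal equations by hand
        prof = _profiles([(10, 100), (15, 100), (5, 100)])
        prof["volume"] = [np.e ** 1, np.e ** 2, np.e ** 3]
        prof = mu.profiles_from_counts(prof["facility_id"], prof["volume"].astype(int),
                                       mis_count=[10, 15, 5])
        x = np.log(prof["volume"].to_numpy(dtype=float))
        y = prof["mis_rate"].to_numpy() * 100
        slope_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        reg = mu.volume_regression(prof, "mis")
        assert reg.slope == pytest.approx(slope_hand, abs=1e-10)
        assert reg.intercept == pytest.approx(y.mean() - slope_hand * x.mean(), abs=1e-8)

    def test_volume_independent_truth_centres_on_zero(self):
        # when the misutilization rate is unrelated to volume the slope is
        # unbiased and its classical CI covers 0 in most replicates (binomial
        # noise at small volumes makes the homoskedastic interval run a
        # little below nominal, so coverage is checked at 0.8)
        rng = np.random.default_rng(31)
        covered, slopes = 0, []
        reps = 20
        for i in range(reps):
            cfg = mu.SyntheticConfig(n_facilities=300, total_visits_target=15000,
                                     seed=1000 + i)
            vol = mu.generate_facility_volumes(cfg)["volume"].to_numpy()
            counts = rng.binomial(vol, 0.17)
            prof = mu.profiles_from_counts([f"F{i}" for i in range(len(vol))], vol,
                                           mis_count=counts)
            reg = mu.volume_regression(prof, "mis")
            slopes.append(reg.slope)
            x = sm.add_constant(np.log(vol.astype(float)))
            res = sm.OLS(prof["mis_rate"].to_numpy() * 100, x).fit()
            lo, hi = res.conf_int()[1]
            covered += lo <= 0 <= hi
        assert abs(np.mean(slopes)) <= 3 * np.std(slopes, ddof=1) / np.sqrt(reps)
        assert covered / reps >= 0.8

    def test_constant_volumes_rejected(self):
        prof = _profiles([(1, 50), (2, 50), (3, 50)])
        with pytest.raises(ValueError):
            mu.volume_regression(prof, "mis")


class TestExtremeTables:
    def test_all_below_min_volume_empty(self):
        prof = _profiles([(1, 10), (2, 20)])
        tables = mu.extreme_tables(prof, min_volume=30)
        assert len(tables["mis"]["top"]) == 0

    def test_exactly_k_rows(self):
        prof = _profiles([(i, 50) for i in range(12)])
        tables = mu.extreme_tables(prof, min_volume=30, k=10)
        assert len(tables["mis"]["top"]) == 10
        assert len(tables["mis"]["bottom"]) == 10

    def test_bottom_admits_zero_rates(self):
        prof = _profiles([(0, 32), (0, 49), (0, 55), (9, 40), (12, 60)])
        bottom = mu.extreme_tables(prof, min_volume=30, k=3)["mis"]["bottom"]
        assert (bottom["mis_rate"] == 0).all()
        # ties broken by volume descending
        assert list(bottom["volume"]) == [55, 49, 32]
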