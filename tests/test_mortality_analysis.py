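import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from mirounga import mortality_analysis as ma
from mirounga import synthetic_data as sd


def _trans(classes):
    return pd.DataFrame({"day": np.arange(len(classes)), "best_class": classes})


class TestAttributeTagFate:
    def test_transmitting_to_return_is_survival(self):
        fate = ma.attribute_tag_fate(_trans(["3"] * 100), [], trip_days=100)
        assert fate.outcome == "survived_returned"
        assert not fate.stopped_at_sea

    def test_stopped_but_resighted_is_tag_failure(self):
        fate = ma.attribute_tag_fate(_trans(["3"] * 50), ["2011-02-01"], trip_days=100)
        assert fate.outcome == "survived_resighted_later"
        assert fate.stopped_at_sea

    def test_monotone_class_decline_is_tag_failure(self):
        decline = ["3"] * 10 + ["2"] * 8 + ["1"] * 6 + ["0"] * 4 + ["B"] * 2
        fate = ma.attribute_tag_fate(_trans(["3"] * 30 + decline), [], trip_days=120)
        assert fate.quality_degrading
        assert fate.outcome == "tag_failure"

    def test_trend_free_record_with_no_resight_is_death(self):
        fate = ma.attribute_tag_fate(
            _trans(sd._palindrome_classes(60)), [], trip_days=120
        )
        assert not fate.quality_degrading
        assert fate.outcome == "died"

    def test_shuffled_classes_rarely_read_as_degrading(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(100):
            classes = list(rng.choice(["3", "2", "1", "0", "A", "B"], size=60))
            fate = ma.attribute_tag_fate(_trans(classes), [], trip_days=120)
            hits += fate.quality_degrading
        assert hits <= 12  # one-sided alpha = 0.05

    def test_empty_record_rejected(self):
        with pytest.raises(ValueError):
            ma.attribute_tag_fate(_trans([]).iloc[0:0], [], trip_days=10)

    def test_outcomes_are_exhaustive_and_exclusive(self, small_cohort):
        att = ma.attribute_cohort(small_cohort.fates, small_cohort.transmissions, small_cohort.resights)
        assert att["outcome"].isin(ma.OUTCOMES).all()
        assert len(att) == len(small_cohort.fates)
        per_sex = att.groupby("sex").size().sum()
        assert per_sex == len(att)


class TestMannKendall:
    def test_monotone_decline_strongly_significant(self):
        assert ma.mann_kendall_onesided(np.arange(30)[::-1]) < 1e-6

    def test_monotone_rise_not_flagged(self):
        assert ma.mann_kendall_onesided(np.arange(30)) > 0.95

    def test_palindrome_is_exactly_trend_free(self):
        ranks = [5, 3, 1, 0, 1, 3, 5]
        assert ma.mann_kendall_onesided(np.array(ranks, float)) == pytest.approx(0.5, abs=0.05)


class TestLastLocation:
    def _hourly(self, stop_at):
        lat = np.concatenate([37.0 + 0.1 * np.arange(20), np.full(10, 39.0),
                              39.0 - 0.1 * np.arange(20)])
        h = pd.DataFrame(
            {
                "timestamp": pd.date_range("2010-01-01", periods=50, freq="h"),
                "lat": lat,
                "lon": np.full(50, -124.0),
                "speed_kmh": np.full(50, 3.0),
            }
        )
        return h.iloc[:stop_at]

    shelf = (np.linspace(30, 50, 20), np.full(20, -124.0))

    def test_death_at_apex_is_farthest_point(self):
        loc = ma.last_location_metrics(self._hourly(25), (37.0, -124.0), *self.shelf)
        assert loc.trip_portion == "farthest point"

    def test_death_on_outbound_leg(self):
        loc = ma.last_location_metrics(self._hourly(10), (37.0, -124.0), *self.shelf)
        assert loc.trip_portion == "outward"

    def test_death_on_return_leg(self):
        loc = ma.last_location_metrics(self._hourly(45), (37.0, -124.0), *self.shelf)
        assert loc.trip_portion == "return"

    def test_final_position_on_isobath_distance_zero(self):
        loc = ma.last_location_metrics(self._hourly(25), (37.0, -124.0), *self.shelf)
        assert loc.shelf_distance_km < 1e-6
        assert loc.transit_rate_m_s == pytest.approx(3.0 / 3.6)

    def test_near_shelf_death_fraction_matches_construction(self):
        """Deaths placed on the shelf-side track are recovered as near-shelf."""
        rng = np.random.default_rng(1)
        near = 0
        n = 40
        for _ in range(n):
            stop = int(rng.integers(5, 49))
            loc = ma.last_location_metrics(self._hourly(stop), (37.0, -124.0), *self.shelf)
            near += loc.shelf_distance_km <= 30.0
        assert near == n  # the whole track lies on the isobath by construction


class TestMortalityModels:
    def _cohort(self):
        tab, trans, res = sd.make_reference_cohort_fixture()
        return ma.attribute_cohort(tab, trans, res)

    def test_sex_only_model_recovers_group_death_fractions(self):
        att = self._cohort()
        models = ma.fit_mortality_models(att)
        sex_only = [m for m in models if m.terms == ("sex",)][0]
        p_m = ma.mortality_probability(sex_only, att, "male")
        p_f = ma.mortality_probability(sex_only, att, "female")
        assert p_m["probability"] == pytest.approx(17 / 39, abs=1e-6)
        assert p_f["probability"] == pytest.approx(22 / 178, abs=1e-6)
        for p in (p_m, p_f):
            assert 0.0 < p["ci_low"] < p["probability"] < p["ci_high"] < 1.0

    def test_ranking_includes_all_sex_subsets_with_delta_aic(self):
        att = self._cohort()
        models = ma.fit_mortality_models(att)
        assert {m.terms for m in models} == {
            ("sex",), ("sex", "trip"), ("sex", "year"), ("sex", "trip", "year")
        }
        assert models[0].delta_aic == 0.0
        assert np.isfinite(models[0].hosmer_lemeshow_p)
        assert models[0].lrt_p_vs_null < 0.001  # sex matters strongly

    def test_irls_matches_likelihood_grid_refinement(self):
        """IRLS estimates agree with brute-force likelihood search to 1e-4."""
        att = self._cohort()
        y = att["died"].to_numpy(float)
        x = (att["sex"] == "male").to_numpy(float)
        X = np.column_stack([np.ones_like(x), x])
        models = ma.fit_mortality_models(att)
        sex_only = [m for m in models if m.terms == ("sex",)][0]
        fitted = np.array(sex_only.result.params)
        # iterative grid refinement around a coarse box
        centre = np.array([0.0, 0.0])
        width = np.array([6.0, 6.0])
        for _ in range(12):
            b0 = np.linspace(centre[0] - width[0], centre[0] + width[0], 21)
            b1 = np.linspace(centre[1] - width[1], centre[1] + width[1], 21)
            vals = [(ma.logistic_nll([a, b], X, y), a, b) for a in b0 for b in b1]
            _, a_best, b_best = min(vals)
            centre = np.array([a_best, b_best])
            width = width / 4.0
        assert np.allclose(np.sort(fitted), np.sort(centre), atol=1e-4) or np.allclose(
            fitted, centre, atol=1e-4
        )

    def test_independent_outcome_keeps_null_close(self):
        rng = np.random.default_rng(3)
        wins = 0
        for rep in range(30):
            n = 120
            df = pd.DataFrame(
                {
                    "sex": np.repeat(["male", "female"], n // 2),
                    "trip": "post_breeding",
                    "year": "2010",
                    "died": rng.binomial(1, 0.3, n),
                }
            )
            if df["died"].nunique() < 2:
                continue
            import statsmodels.api as sm
            import statsmodels.formula.api as smf

            sex_fit = smf.glm("died ~ C(sex)", data=df, family=sm.families.Binomial()).fit()
            null_fit = smf.glm("died ~ 1", data=df, family=sm.families.Binomial()).fit()
            wins += (null_fit.aic - sex_fit.aic) <= 2.0
        assert wins >= 24  # null competitive in most replicates under the null

    def test_single_outcome_level_rejected(self):
        df = pd.DataFrame({"sex": ["male", "female"] * 5, "died": [0] * 10})
        with pytest.raises(ValueError):
            ma.fit_mortality_models(df)


class TestHosmerLemeshow:
    def test_well_calibrated_model_rejected_at_nominal_rate(self):
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            p = rng.uniform(0.05, 0.9, 2000)
            y = rng.binomial(1, p)
            _, pval, _ = ma.hosmer_lemeshow(y, p)
            rejections += pval < 0.05
        assert rejections <= 4

    def test_miscalibrated_model_rejected(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.05, 0.9, 2000)
        y = rng.binomial(1, np.clip(p * 0.4, 0, 1))
        _, pval, _ = ma.hosmer_lemeshow(y, p)
        assert pval < 0.001


class TestCompareDeathLocations:
    def test_tiny_vectors_exact_u_and_p(self):
        male = pd.DataFrame({"shelf_distance_km": [1.0, 2.0, 3.0], "transit_rate_m_s": [1, 2, 3]})
        female = pd.DataFrame({"shelf_distance_km": [4.0, 5.0, 6.0], "transit_rate_m_s": [4, 5, 6]})
        out = ma.compare_death_locations(male, female)
        row = out[out["metric"] == "shelf_distance_km"].iloc[0]
        assert row["u_statistic"] == 0.0
        # exact two-sided p from full enumeration of C(6,3)=20 labelings
        assert row["p_value"] == pytest.approx(2 / 20, rel=1e-9)

    def test_separated_groups_significant_after_bonferroni(self):
        rng = np.random.default_rng(6)
        male = pd.DataFrame(
            {"shelf_distance_km": rng.normal(60, 10, 17), "transit_rate_m_s": rng.uniform(0, 1, 17)}
        )
        female = pd.DataFrame(
            {"shelf_distance_km": rng.normal(470, 50, 22), "transit_rate_m_s": rng.uniform(0, 1, 22)}
        )
        out = ma.compare_death_locations(male, female)
        row = out[out["metric"] == "shelf_distance_km"].iloc[0]
        assert row["p_adjusted"] < 0.001

    def test_identical_distributions_not_significant(self):
        vals = np.linspace(1, 50, 12)
        male = pd.DataFrame({"shelf_distance_km": vals, "transit_rate_m_s": vals})
        female = pd.DataFrame({"shelf_distance_km": vals, "transit_rate_m_s": vals})
        out = ma.compare_death_locations(male, female)
        assert (out["p_value"] > 0.9).all()

    def test_too_few_deaths_rejected(self):
        male = pd.DataFrame({"shelf_distance_km": [1.0], "transit_rate_m_s": [1.0]})
        female = pd.DataFrame({"shelf_distance_km": [1.0, 2.0, 3.0], "transit_rate_m_s": [1, 2, 3]})
        with pytest.raises(ValueError):
            ma.compare_death_locations(male, female)
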