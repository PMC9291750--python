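import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import dispersalkit as dk
from dispersalkit.models import (
    DispersalTypeModel,
    RandomInterceptLogit,
    aicc,
    candidate_model_set,
    compare_groups,
    fit_linear,
    fit_model_set,
    rank_models,
    select_potential_dispersers,
    summarize_types,
)

TABLE3 = {
    "social": {"intercept": -2.62, "sexM": 2.01, "dist_town": 0.01},
    "spatial": {"intercept": -3.06, "sexM": 0.74, "dist_town": 0.11},
    "social-and-spatial": {"intercept": -3.01, "sexM": 2.56, "dist_town": 0.07},
}


class TestInclusionFilter:
    def _detections(self, sightings):
        """sightings: {id: [(year, as_calf), ...]}."""
        rows = []
        for cid, obs in sightings.items():
            for k, (year, as_calf) in enumerate(obs):
                rows.append(
                    {"id": cid, "occasion": (year - 2012) * 10 + k, "year": year,
                     "age_class": "calf" if as_calf else "subadult"}
                )
        return pd.DataFrame(rows)

    def test_continuously_detected_calf_included(self):
        det = self._detections(
            {"a": [(y, y == 2012) for y in range(2012, 2019)]}
        )
        assert select_potential_dispersers(det, (2012, 2013)) == ["a"]

    def test_gap_interval_excluded(self):
        # missing from 2015-2017 entirely
        det = self._detections(
            {"a": [(2012, True), (2013, False), (2014, False), (2018, False)],
             "b": [(y, y == 2012) for y in range(2012, 2019)]}
        )
        assert select_potential_dispersers(det, (2012, 2013)) == ["b"]

    def test_first_sighted_as_subadult_excluded(self):
        det = self._detections(
            {"a": [(y, False) for y in range(2012, 2019)],
             "b": [(y, y == 2013) for y in range(2013, 2019)]}
        )
        assert select_potential_dispersers(det, (2012, 2013)) == ["b"]

    def test_matches_brute_force_on_simulated_gaps(self):
        rng = np.random.default_rng(3)
        sightings = {}
        for i in range(60):
            years = sorted(
                rng.choice(range(2012, 2019), size=rng.integers(1, 8),
                           replace=False)
            )
            sightings[f"c{i:02d}"] = [
                (int(y), k == 0 and y in (2012, 2013))
                for k, y in enumerate(years)
            ]
        det = self._detections(sightings)
        got = select_potential_dispersers(det, (2012, 2013))
        # independent brute-force re-implementation
        expected = []
        for cid, obs in sightings.items():
            ys = {y for y, _ in obs}
            first_year, first_calf = obs[0]
            if not (first_calf and first_year in (2012, 2013)):
                continue
            if all(ys & set(range(s, s + 3)) for s in range(2012, 2017)):
                expected.append(cid)
        assert got == sorted(expected)


class TestRandomInterceptLogit:
    def test_reduces_to_plain_logistic_without_community_variance(self):
        d = dk.simulate_binary_records(500, intercept=-1.0, beta_sex=1.85,
                                       community_sd=0.0, seed=3)
        r = RandomInterceptLogit.from_dataframe(
            d, "dispersed", ["sex"], "community"
        ).fit()
        plain = sm.Logit(
            d["dispersed"].to_numpy(),
            sm.add_constant((d["sex"] == "M").astype(float).to_numpy()),
        ).fit(disp=0)
        assert abs(r.params[1] - plain.params[1]) < 2 * plain.bse[1]
        assert r.sigma < 0.05

    def test_recovers_planted_sex_effect(self):
        """Male-dispersal log odds of 1.85 with a weak community effect are
        recovered within 2 SE at n = 500."""
        d = dk.simulate_binary_records(500, intercept=-1.0, beta_sex=1.85,
                                       community_sd=0.3, seed=4)
        r = RandomInterceptLogit.from_dataframe(
            d, "dispersed", ["sex"], "community"
        ).fit()
        assert abs(r.params[1] - 1.85) < 2 * r.bse[1]
        assert r.pvalues[1] < 0.001
        assert "random-intercept SD" in r.summary()

    def test_constant_response_rejected(self):
        d = pd.DataFrame({"dispersed": [0] * 20, "sex": ["M", "F"] * 10,
                          "community": [0, 1] * 10})
        with pytest.raises(ValueError):
            RandomInterceptLogit.from_dataframe(d, "dispersed", ["sex"],
                                                "community")


class TestDispersalTypeModel:
    def test_two_category_case_matches_plain_logistic(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 400)
        y = rng.random(400) < 1 / (1 + np.exp(-(-0.5 + 0.8 * x)))
        rec = pd.DataFrame(
            {"dispersal_class": np.where(y, "social", "none"), "dist_town": x}
        )
        res = DispersalTypeModel(rec, ["dist_town"]).fit()
        plain = sm.Logit(y.astype(float), sm.add_constant(x)).fit(disp=0)
        np.testing.assert_allclose(
            res.params["social"].to_numpy(), plain.params, atol=1e-4
        )
        np.testing.assert_allclose(
            res.bse["social"].to_numpy(), plain.bse, rtol=1e-3
        )

    def test_published_coefficients_give_published_risk_ratios(self):
        rec = dk.simulate_multinomial_records(200, TABLE3, seed=0)
        res = DispersalTypeModel(rec, ["sex", "dist_town"]).fit()
        rrr = np.exp(res.params)  # same transform the results object exposes
        pd.testing.assert_frame_equal(rrr, res.rrr)

    def test_parameter_recovery_within_2se(self):
        rec = dk.simulate_multinomial_records(2000, TABLE3, seed=0)
        res = DispersalTypeModel(rec, ["sex", "dist_town"]).fit()
        for cls, co in TABLE3.items():
            for term, key in [("const", "intercept"), ("sexM", "sexM"),
                              ("dist_town", "dist_town")]:
                assert (
                    abs(res.params.loc[term, cls] - co[key])
                    < 2 * res.bse.loc[term, cls]
                )

    def test_empty_category_warns(self):
        rec = pd.DataFrame(
            {"dispersal_class": ["none"] * 30 + ["social"] * 20,
             "dist_town": np.r_[np.zeros(30), np.ones(20)]}
        )
        with pytest.warns(UserWarning, match="structural zero"):
            DispersalTypeModel(rec, ["dist_town"])


class TestPredictedProbabilities:
    @pytest.fixture()
    def fitted(self, _fitted_cache=[]):
        if not _fitted_cache:
            rec = dk.simulate_multinomial_records(800, TABLE3, seed=2)
            _fitted_cache.append((rec, DispersalTypeModel(rec, ["sex", "dist_town"]).fit()))
        return _fitted_cache[0]

    def test_probabilities_sum_to_one(self, fitted):
        _, res = fitted
        pp = res.predicted_probabilities("dist_town", [5.0, 15.0, 25.0])
        sums = pp[["none", "social", "spatial", "social-and-spatial"]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_null_model_curves_are_flat_category_frequencies(self, fitted):
        rec, _ = fitted
        null = DispersalTypeModel(rec, []).fit()
        pp = null.predicted_probabilities("dist_town", [5.0, 25.0])
        freq = rec["dispersal_class"].value_counts(normalize=True)
        for cls in ["none", "social", "spatial", "social-and-spatial"]:
            np.testing.assert_allclose(pp[cls], freq[cls], atol=1e-6)

    def test_planted_positive_effect_gives_monotone_curves(self, fitted):
        _, res = fitted
        grid = np.linspace(4.0, 28.0, 6)
        pp = res.predicted_probabilities("dist_town", grid)
        for sex in ["F", "M"]:
            curve = pp[pp["sex"] == sex].sort_values("dist_town")
            assert curve["spatial"].is_monotonic_increasing
            assert curve["social-and-spatial"].is_monotonic_increasing

    def test_extrapolation_warns(self, fitted):
        _, res = fitted
        with pytest.warns(UserWarning, match="beyond observed range"):
            res.predicted_probabilities("dist_town", [1000.0])


class TestModelRanking:
    def test_aicc_small_sample_correction(self):
        assert aicc(0.0, 3, 137) - (-2 * 0.0 + 2 * 3) == pytest.approx(
            0.180, abs=5e-4
        )

    def test_identical_models_share_weight(self):
        rec = dk.simulate_multinomial_records(300, TABLE3, seed=1)
        fit = DispersalTypeModel(rec, ["sex"]).fit()
        tab = rank_models({"a": fit, "b": fit})
        np.testing.assert_allclose(tab["weight"], 0.5)

    def test_true_model_beats_null_decisively(self):
        rec = dk.simulate_multinomial_records(2000, TABLE3, seed=0)
        fits = {
            "sex+dist_town": DispersalTypeModel(rec, ["sex", "dist_town"]).fit(),
            "null": DispersalTypeModel(rec, []).fit(),
        }
        tab = rank_models(fits)
        assert tab["model"].iloc[0] == "sex+dist_town"
        assert tab["weight"].iloc[0] > 0.9
        assert tab["weight"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_fitted_loglik_never_below_null(self):
        rec = dk.simulate_multinomial_records(400, TABLE3, seed=6)
        null = DispersalTypeModel(rec, []).fit()
        for preds in (["sex"], ["dist_town"], ["sex", "dist_town"]):
            assert DispersalTypeModel(rec, preds).fit().llf >= null.llf - 1e-6

    def test_differing_n_is_an_error(self):
        rec = dk.simulate_multinomial_records(300, TABLE3, seed=1)
        with pytest.raises(ValueError, match="differing n"):
            rank_models({
                "a": DispersalTypeModel(rec, []).fit(),
                "b": DispersalTypeModel(rec.head(200), []).fit(),
            })

    def test_candidate_set_has_twenty_models(self):
        specs = candidate_model_set()
        assert len(specs) == 20
        assert ("null", []) in specs

    def test_correlated_pairs_dropped(self):
        rec = dk.simulate_multinomial_records(300, TABLE3, seed=2)
        rec["dist_boma"] = rec["dist_town"] * 0.9 + 0.1  # r ~ 1
        rec["forage"] = np.random.default_rng(0).uniform(0, 1, len(rec))
        rec["density"] = np.random.default_rng(1).uniform(0, 1, len(rec))
        with pytest.warns(UserWarning, match="dropped"):
            fits = fit_model_set(
                rec, lambda d, p: DispersalTypeModel(d, p).fit()
            )
        assert "dist_town+dist_boma" not in fits
        assert "sex+dist_town" in fits


class TestLinearModels:
    def test_recovers_planted_distance_effect(self):
        rng = np.random.default_rng(5)
        n = 300
        rec = pd.DataFrame({
            "sex": np.where(rng.random(n) < 0.5, "M", "F"),
            "dist_town": rng.uniform(2, 30, n),
        })
        rec["final_km"] = (
            3.0 + 2.0 * (rec["sex"] == "M") + 0.3 * rec["dist_town"]
            + rng.normal(0, 2, n)
        )
        res = fit_linear(rec, "final_km", ["sex", "dist_town"])
        assert abs(res.params["sexM"] - 2.0) < 2 * res.bse["sexM"]
        assert abs(res.params["dist_town"] - 0.3) < 2 * res.bse["dist_town"]
        assert res.k_params == 4  # intercept, two slopes, residual variance


class TestCompareGroups:
    def test_identical_samples_have_zero_t(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = compare_groups(x, x.copy())
        assert res.statistic == pytest.approx(0.0)

    def test_location_shift_detected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        res = compare_groups(x, x + 1.0)
        assert res.pvalue < 1e-3

    def test_welch_df_satterthwaite(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
        res = compare_groups(x, y)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert res.df == pytest.approx(ref.df)

    def test_wilcoxon_close_to_exhaustive_permutation(self):
        """Tie-corrected normal approximation tracks the exact rank-sum
        permutation distribution on small fixed vectors."""
        x = np.array([1.2, 2.3, 3.1, 4.5, 2.2, 3.3, 1.9, 2.8, 3.7, 2.5])
        y = np.array([2.9, 3.8, 4.4, 5.1, 3.2, 4.0, 2.7, 4.8, 3.9, 4.6])
        res = compare_groups(x, y, method="wilcoxon")
        exact = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.pvalue == pytest.approx(exact.pvalue, abs=0.01)

    def test_degenerate_zero_variance(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 1.0, 1.0], [1.0, 1.0])


class TestSummarizeTypes:
    def test_published_counts_reproduce_published_shares(self, printed_count_records):
        s = summarize_types(printed_count_records)
        assert s.dispersed.loc["M", "n_dispersed"] == 46
        assert s.dispersed.loc["M", "fraction"] == pytest.approx(46 / 67)
        assert round(100 * s.dispersed.loc["M", "fraction"]) == 69
        assert round(100 * s.dispersed.loc["F", "fraction"]) == 26
        assert s.share_among_dispersers.loc["F", "social"] == pytest.approx(
            4 / 18
        )
        assert s.share_among_dispersers.loc["M", "social"] == pytest.approx(
            12 / 46
        )

    def test_empty_class_reported_as_zero(self):
        rec = pd.DataFrame(
            {"sex": ["F", "F"], "dispersal_class": ["none", "social"]}
        )
        s = summarize_types(rec)
        assert s.counts.loc["F", "spatial"] == 0
        assert s.proportions.loc["F", "spatial"] == 0.0

    def test_distances_averaged_per_class(self):
        rec = pd.DataFrame({
            "sex": ["M"] * 4,
            "dispersal_class": ["none", "none", "spatial", "spatial"],
            "final_km": [2.0, 4.0, 10.0, 14.0],
            "max_km": [3.0, 5.0, 12.0, 16.0],
        })
        s = summarize_types(rec)
        assert s.mean_final_km.loc["M", "spatial"] == 12.0
        assert s.mean_max_km.loc["M", "none"] == 4.0
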