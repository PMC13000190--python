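"""Mixed models of lnPb: AICc, all-subsets selection, variable importance
and the year-effect decomposition."""

import numpy as np
import pandas as pd
import pytest

from condorlead import exposure
from condorlead.exposure import (aicc, admissible_subsets, akaike_weights,
                                 all_subsets, fit_exposure_model,
                                 variable_importance,
                                 year_effect_decomposition)


class TestAicc:
    def test_worked_arithmetic(self):
        # -2(-100) + 2*5 + 2*5*6/94
        assert aicc(-100.0, 5, 100) == pytest.approx(210.0 + 60.0 / 94.0)

    def test_k_zero_is_minus_two_loglik(self):
        assert aicc(-123.4, 0, 50) == pytest.approx(246.8)

    def test_limit_to_aic(self):
        assert aicc(-100.0, 5, 10**9) == pytest.approx(210.0, abs=1e-5)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)

    def test_weights_normalise(self):
        w = akaike_weights([100.0, 101.0, 105.0])
        assert w.sum() == pytest.approx(1.0)
        assert w[0] > w[1] > w[2]


def simulate_lmm(n_id=40, n_yr=8, reps=4, beta_targeted=0.8,
                 beta_proffered=-1.0, sd_id=0.5, sd_yr=0.3, sd_e=0.6,
                 seed=0):
    """Crossed random-intercept LMM data with known coefficients."""
    rng = np.random.default_rng(seed)
    id_re = rng.normal(0, sd_id, n_id)
    yr_re = rng.normal(0, sd_yr, n_yr)
    rows = []
    for i in range(n_id):
        for y in range(n_yr):
            for _ in range(reps):
                prof = rng.uniform(0, 1)
                noise_cov = rng.uniform(0, 1)
                targ = float(rng.random() < 0.2)
                lnpb = (1.5 + beta_targeted * targ + beta_proffered * prof
                        + id_re[i] + yr_re[y] + rng.normal(0, sd_e))
                rows.append({"ID": f"C{i}", "Bioyear": 2000 + y,
                             "Targeted": targ, "Proffered": prof,
                             "Noise": noise_cov, "lnPb": lnpb})
    return pd.DataFrame(rows)


class TestFitExposureModel:
    def test_coefficient_recovery_within_2se(self):
        df = simulate_lmm(seed=1)
        fit = fit_exposure_model(df, ("Targeted", "Proffered"))
        coef = fit.coefficients.set_index("term")
        for term, truth in [("Targeted", 0.8), ("Proffered", -1.0)]:
            est, se = coef.loc[term, "estimate"], coef.loc[term, "se"]
            assert abs(est - truth) < 2 * se

    def test_zero_variance_bioyear_component_vanishes(self):
        df = simulate_lmm(sd_yr=0.0, seed=2)
        fit = fit_exposure_model(df, ("Targeted",))
        assert fit.vc["Bioyear"] < 0.01

    def test_intercept_only_equals_grand_mean_balanced(self):
        df = simulate_lmm(n_id=20, n_yr=5, reps=3, beta_targeted=0.0,
                          beta_proffered=0.0, seed=3)
        fit = fit_exposure_model(df, ())
        grand = df["lnPb"].mean()
        assert fit.coefficients["estimate"].iloc[0] == \
            pytest.approx(grand, abs=0.05)

    def test_conditional_r2_at_least_marginal(self):
        df = simulate_lmm(seed=4)
        fit = fit_exposure_model(df, ("Targeted", "Proffered"))
        assert fit.r2_conditional >= fit.r2_marginal
        assert np.isfinite(fit.aicc)

    def test_rank_deficiency_names_aliased_column(self):
        df = simulate_lmm(n_id=10, n_yr=3, reps=2, seed=5)
        df["ProfferedCopy"] = df["Proffered"]
        with pytest.raises(ValueError, match="ProfferedCopy"):
            fit_exposure_model(df, ("Proffered", "ProfferedCopy"))

    def test_interaction_requires_main_effects(self):
        df = simulate_lmm(n_id=10, n_yr=3, reps=2, seed=6)
        with pytest.raises(ValueError, match="main effects"):
            fit_exposure_model(df, ("Targeted:Proffered",))

    def test_wald_90_ci_uses_1645_se(self):
        df = simulate_lmm(n_id=15, n_yr=4, reps=2, seed=7)
        fit = fit_exposure_model(df, ("Targeted",))
        row = fit.coefficients.set_index("term").loc["Targeted"]
        assert row["ci90_high"] - row["estimate"] == \
            pytest.approx(1.6449 * row["se"], rel=1e-3)


class TestAllSubsets:
    def test_enumeration_counts(self):
        assert len(admissible_subsets(["A", "B"])) == 4
        # interaction admissible only with both mains present
        assert len(admissible_subsets(["A", "B", "A:B"])) == 5

    def test_weights_sum_to_one_and_ranking(self):
        df = simulate_lmm(n_id=25, n_yr=5, reps=3, seed=8)
        tab = all_subsets(df, ["Targeted", "Proffered"])
        assert tab["weight"].sum() == pytest.approx(1.0)
        assert (tab["aicc"].diff().dropna() >= 0).all()
        # both effects are strong: the full model should win
        assert set(tab["terms"].iloc[0]) == {"Targeted", "Proffered"}

    def test_true_subset_top_ranked_across_replicates(self):
        wins = 0
        n_rep = 5
        for s in range(n_rep):
            df = simulate_lmm(n_id=25, n_yr=5, reps=3, seed=100 + s)
            tab = all_subsets(df, ["Targeted", "Proffered", "Noise"])
            if set(tab["terms"].iloc[0]) == {"Targeted", "Proffered"}:
                wins += 1
        assert wins >= int(0.8 * n_rep)

    def test_ranking_invariant_to_term_order(self):
        df = simulate_lmm(n_id=20, n_yr=4, reps=2, seed=9)
        t1 = all_subsets(df, ["Targeted", "Proffered"])
        t2 = all_subsets(df, ["Proffered", "Targeted"])
        assert [set(t) for t in t1["terms"]] == [set(t) for t in t2["terms"]]
        assert np.allclose(t1["aicc"], t2["aicc"], atol=1e-6)

    def test_model_cap_enforced(self):
        df = simulate_lmm(n_id=10, n_yr=3, reps=2, seed=10)
        with pytest.raises(ValueError, match="cap"):
            all_subsets(df, ["Targeted", "Proffered", "Noise"],
                        max_models=3)

    def test_nested_flag_marks_uninformative_extensions(self):
        df = simulate_lmm(n_id=25, n_yr=5, reps=3, seed=11)
        tab = all_subsets(df, ["Targeted", "Proffered", "Noise"])
        top = set(tab["terms"].iloc[0])
        for i in range(1, len(tab)):
            if top < set(tab["terms"].iloc[i]):
                assert tab["nested"].iloc[i]


class TestVariableImportance:
    def test_term_in_every_model_sums_to_one(self):
        df = simulate_lmm(n_id=20, n_yr=4, reps=2, seed=12)
        tab = all_subsets(df, ["Targeted", "Proffered"])
        # restrict to models containing Targeted
        sub = tab[[("Targeted" in t) for t in tab["terms"]]].copy()
        sub["weight"] = akaike_weights(sub["aicc"])
        imp = variable_importance(sub)
        assert imp.set_index("term").loc["Targeted", "sum_weights"] == \
            pytest.approx(1.0)

    def test_largest_coefficient_ratio_is_one(self):
        df = simulate_lmm(seed=13)
        imp = variable_importance(
            all_subsets(df, ["Targeted", "Proffered"]))
        assert imp["ratio_full"].max() == pytest.approx(1.0)
        assert ((imp["ratio_full"] >= 0) & (imp["ratio_full"] <= 1)).all()
        assert ((imp["sum_weights"] >= 0) & (imp["sum_weights"] <= 1)).all()

    def test_hand_computed_two_model_table(self):
        # constructed table: weights 0.75/0.25, standardised coefs 0.4 / 0.2
        def fake_fit(terms, coefs):
            std = pd.DataFrame({"term": list(terms),
                                "estimate": coefs, "se": [0.1] * len(terms)})
            f = exposure.FitResult.__new__(exposure.FitResult)
            f.terms = terms
            f.std_coefficients = std
            return f
        tab = pd.DataFrame({
            "terms": [("A",), ("A", "B")],
            "weight": [0.75, 0.25],
            "fit": [fake_fit(("A",), [0.4]), fake_fit(("A", "B"),
                                                      [0.4, 0.2])],
        })
        imp = variable_importance(tab).set_index("term")
        assert imp.loc["A", "sum_weights"] == pytest.approx(1.0)
        assert imp.loc["B", "sum_weights"] == pytest.approx(0.25)
        # full average for B: 0.75*0 + 0.25*0.2 = 0.05; subset average 0.2
        assert imp.loc["B", "coef_full"] == pytest.approx(0.05)
        assert imp.loc["B", "coef_subset"] == pytest.approx(0.2)
        assert imp.loc["B", "ratio_full"] == pytest.approx(0.05 / 0.4)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            variable_importance(pd.DataFrame({"terms": [], "weight": [],
                                              "fit": []}))


def simulate_year_shift(n_id=30, reps=6, shift=-0.8, behavior_driver=False,
                        seed=0):
    """Post-2008 drop in lnPb, injected directly or via declining Proffered."""
    rng = np.random.default_rng(seed)
    id_re = rng.normal(0, 0.4, n_id)
    rows = []
    years = np.arange(2004, 2012)
    for i in range(n_id):
        for y in years:
            for _ in range(reps):
                targ = float(rng.random() < 0.2)
                if behavior_driver:
                    prof = np.clip(0.8 - 0.08 * (y - 2004)
                                   + rng.normal(0, 0.05), 0, 1)
                    lnpb = 2.0 + 0.5 * targ - 2.0 * prof + id_re[i] \
                        + rng.normal(0, 0.5)
                else:
                    prof = rng.uniform(0, 1)
                    lnpb = (2.0 + 0.5 * targ
                            + (shift if y >= 2008 else 0.0)
                            + id_re[i] + rng.normal(0, 0.5))
                rows.append({"ID": f"C{i}", "Bioyear": y, "Targeted": targ,
                             "Proffered": prof, "lnPb": lnpb})
    return pd.DataFrame(rows)


class TestYearEffectDecomposition:
    def test_base_model_recovers_injected_shift(self):
        df = simulate_year_shift(shift=-0.8, seed=1)
        out = year_effect_decomposition(df, {"base": ["Targeted"]})
        post = out[out["bioyear"] >= 2008]
        assert np.all(post["ci90_low"] < -0.8) and \
            np.all(-0.8 < post["ci90_high"])

    def test_saturated_truth_leaves_residual_years_near_zero(self):
        df = simulate_year_shift(behavior_driver=True, seed=2)
        out = year_effect_decomposition(
            df, {"base": ["Targeted"],
                 "behavior": ["Targeted", "Proffered"]})
        base_sd = out[out["model"] == "base"]["beta"].std()
        beh = out[out["model"] == "behavior"]["beta"]
        # behaviour drove the trend: residual year effects flatten
        assert beh.std() < 0.5 * base_sd
        assert beh.abs().max() < 0.3

    def test_noise_covariate_leaves_year_effects_unchanged(self):
        df = simulate_year_shift(shift=-0.6, seed=3)
        rng = np.random.default_rng(4)
        df["Noise"] = rng.uniform(0, 1, len(df))
        out = year_effect_decomposition(
            df, {"base": ["Targeted"], "noise": ["Targeted", "Noise"]})
        b = out[out["model"] == "base"].set_index("bioyear")["beta"]
        n = out[out["model"] == "noise"].set_index("bioyear")["beta"]
        assert np.abs(b - n).max() < 0.1

    def test_non_nested_sequence_warns_but_computes(self):
        df = simulate_year_shift(seed=5)
        with pytest.warns(UserWarning, match="not nested"):
            out = year_effect_decomposition(
                df, {"a": ["Targeted"], "b": ["Proffered"]})
        assert len(out) > 0
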