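"""Tests of kin-cohort weights, episode splitting, and Cox wrappers."""

import numpy as np
import pandas as pd
import pytest

from carriermr import cox
from carriermr.survival import (CoxResult, SurvivalError, build_weights,
                                censor_other_class, fit_weighted_cox,
                                interaction_test, menopause_age,
                                split_episodes, subtype_analysis, wald_p)


def incidence_table(rows):
    return pd.DataFrame(rows, columns=["gene", "age_lo", "age_hi", "prob"])


def make_pheno(genes, exit_age, case, family=None):
    n = len(genes)
    return pd.DataFrame({
        "person": [f"P{i}" for i in range(n)],
        "family": family if family is not None else [f"F{i}" for i in range(n)],
        "gene": genes,
        "case": case,
        "age_ovca": np.where(np.asarray(case) == 1, exit_age, np.nan),
        "age_breast": np.nan,
        "age_rrso": np.nan,
        "age_death": np.nan,
        "age_end_followup": np.where(np.asarray(case) == 1, np.nan, exit_age),
        "age_menopause_natural": np.nan,
    })


class TestBuildWeights:
    def test_matching_incidence_gives_unit_weights(self):
        ph = make_pheno(["BRCA1"] * 10, [45.0] * 10,
                        [1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        inc = incidence_table([("BRCA1", 40.0, 50.0, 0.2)])
        w = build_weights(ph, inc)
        assert np.allclose(w, 1.0)

    def test_direct_ratio_weights(self):
        # p_obs = 0.5, p_exp = 0.1 -> case 0.2, non-case 1.8
        ph = make_pheno(["BRCA1"] * 10, [45.0] * 10, [1] * 5 + [0] * 5)
        inc = incidence_table([("BRCA1", 40.0, 50.0, 0.1)])
        w = build_weights(ph, inc)
        assert np.allclose(w[:5], 0.2)
        assert np.allclose(w[5:], 1.8)
        # weighted case fraction equals p_exp exactly
        case = ph["case"].to_numpy()
        assert (w.to_numpy() * case).sum() / w.sum() == pytest.approx(0.1)

    def test_three_stratum_arithmetic(self):
        genes = ["BRCA1"] * 20 + ["BRCA1"] * 20 + ["BRCA2"] * 20
        ages = [42.0] * 20 + [57.0] * 20 + [42.0] * 20
        case = ([1] * 4 + [0] * 16) + ([1] * 10 + [0] * 10) + ([1] * 2 + [0] * 18)
        ph = make_pheno(genes, ages, case)
        inc = incidence_table([
            ("BRCA1", 40.0, 45.0, 0.10), ("BRCA1", 55.0, 60.0, 0.30),
            ("BRCA2", 40.0, 45.0, 0.05),
        ])
        w = build_weights(ph, inc).to_numpy()
        c = np.asarray(case)
        for sl, p_exp in ((slice(0, 20), 0.10), (slice(20, 40), 0.30),
                          (slice(40, 60), 0.05)):
            weighted_cases = (w[sl] * c[sl]).sum()
            assert weighted_cases == pytest.approx(p_exp * w[sl].sum())

    def test_sparse_stratum_merged(self):
        # first band has n=8 < 10: merged with the second band
        genes = ["BRCA1"] * 24
        ages = [42.0] * 8 + [47.0] * 4 + [52.0] * 12
        case = [1, 0, 0, 0, 0, 0, 0, 0] + [1] * 4 + [1, 1, 0, 0] + [0] * 8
        ph = make_pheno(genes, ages, case)
        inc = incidence_table([
            ("BRCA1", 40.0, 45.0, 0.10), ("BRCA1", 45.0, 50.0, 0.20),
            ("BRCA1", 50.0, 55.0, 0.20),
        ])
        w = build_weights(ph, inc)
        c = np.asarray(case)
        # merged stratum (bands 1+2): pooled p_exp = mean(0.10, 0.20)
        merged, cm = w[:12].to_numpy(), c[:12]
        assert (merged * cm).sum() / merged.sum() == pytest.approx(0.15)
        # third band stands alone with its own p_exp
        solo, cs = w[12:].to_numpy(), c[12:]
        assert (solo * cs).sum() / solo.sum() == pytest.approx(0.20)


class TestSplitEpisodes:
    def test_menopause_before_event_splits_rows(self):
        ph = make_pheno(["BRCA1"], [52.0], [1])
        ph["age_menopause_natural"] = 48.0
        eps = split_episodes(ph)
        assert len(eps) == 2
        pre, post = eps.iloc[0], eps.iloc[1]
        assert (pre["start"], pre["stop"], pre["event"],
                pre["postmenopausal"]) == (0.0, 48.0, 0, 0)
        assert (post["start"], post["stop"], post["event"],
                post["postmenopausal"]) == (48.0, 52.0, 1, 1)

    def test_missing_menopause_age_imputed_at_50(self):
        ph = make_pheno(["BRCA1"], [60.0], [0])
        eps = split_episodes(ph)
        assert eps["stop"].tolist() == [50.0, 60.0]
        eps46 = split_episodes(ph, menopause_imputation_age=46.0)
        assert eps46["stop"].tolist() == [46.0, 60.0]

    def test_menopause_after_exit_single_premenopausal_row(self):
        ph = make_pheno(["BRCA1"], [45.0], [1])
        ph["age_menopause_natural"] = 51.0
        eps = split_episodes(ph)
        assert len(eps) == 1
        assert eps.loc[0, "event"] == 1
        assert eps.loc[0, "postmenopausal"] == 0

    def test_rrso_acts_as_surgical_menopause(self):
        ph = make_pheno(["BRCA1"], [60.0], [0])
        ph["age_rrso"] = 44.0
        ph["age_end_followup"] = np.nan
        ph["age_menopause_natural"] = 51.0
        m = menopause_age(ph)
        assert m[0] == 44.0

    def test_six_person_manual_expansion(self, toy_pheno):
        eps = split_episodes(toy_pheno)
        # P0: menop 48 < ovca 52 -> 2 rows; P1: menop 51 < end 60 -> 2 rows
        # P2: no menop age -> split at 50? exit 45 < 50 -> 1 row
        # P3: rrso 47 = exit -> menopause at 47 not before exit -> 1 row
        # P4: exit 38 < imputed 50 -> 1 row; P5: menop 49 < ovca 61 -> 2 rows
        counts = eps.groupby("person").size()
        assert counts.tolist() == [2, 2, 1, 1, 1, 2]
        assert eps["event"].sum() == toy_pheno["case"].sum()
        # follow-up time preserved exactly
        spans = (eps["stop"] - eps["start"]).groupby(eps["person"]).sum()
        exits = toy_pheno[["age_ovca", "age_breast", "age_rrso", "age_death",
                           "age_end_followup"]].min(axis=1)
        assert np.allclose(spans.to_numpy(),
                           exits.set_axis(toy_pheno["person"])
                           .loc[spans.index].to_numpy())
        # event sits on the last row of each case
        last = eps.groupby("person").tail(1).set_index("person")
        assert last.loc["P0", "event"] == 1 and last.loc["P2", "event"] == 1


class TestWaldP:
    @pytest.mark.parametrize("coef,se,expected,digits", [
        (0.127, 0.036, 0.0004, 4),    # height variant near CCDC91
        (-0.203, 0.068, 0.003, 3),    # BMI variant near RASA2
    ])
    def test_reported_wald_values(self, coef, se, expected, digits):
        assert round(wald_p(coef, se), digits) == expected

    def test_zero_coefficient_gives_p_one(self):
        assert wald_p(0.0, 0.1) == 1.0

    def test_nonpositive_se_rejected(self):
        with pytest.raises(SurvivalError):
            wald_p(0.1, 0.0)


class TestFitWeightedCox:
    def test_unweighted_agrees_with_engine_and_ci_definition(self, toy_pheno):
        eps = split_episodes(toy_pheno)
        res = fit_weighted_cox(eps, ["height_cm"], weights=None)
        assert isinstance(res, CoxResult)
        t = res.term("height_cm")
        assert t["ci_lo"] == pytest.approx(
            np.exp(t["coef"] - 1.96 * t["robust_se"]))
        assert 0 < t["p"] <= 1
        assert res.n_events == 3

    def test_reporting_scale_exponentiates_k_times_coef(self, toy_pheno):
        eps = split_episodes(toy_pheno)
        res = fit_weighted_cox(eps, ["height_cm"], weights=None,
                               scale={"height_cm": 10.0})
        t = res.term("height_cm")
        assert t["hr"] == pytest.approx(np.exp(10 * t["coef"]))

    def test_missing_weight_for_person_rejected(self, toy_pheno):
        eps = split_episodes(toy_pheno)
        w = pd.Series([1.0], index=["P0"])
        with pytest.raises(SurvivalError, match="weight"):
            fit_weighted_cox(eps, ["height_cm"], weights=w)


class TestInteraction:
    def test_product_term_detects_generated_interaction(self):
        rng = np.random.default_rng(6)
        n = 4000
        x = rng.normal(size=n)
        m = (rng.uniform(size=n) < 0.5).astype(float)
        eta = 0.2 * x + 0.1 * m + 0.5 * x * m
        t = rng.exponential(np.exp(-eta))
        cmax = np.quantile(t, 0.7)
        eps = pd.DataFrame({
            "person": [f"P{i}" for i in range(n)],
            "family": [f"F{i}" for i in range(n)],
            "start": 0.0, "stop": np.minimum(t, cmax),
            "event": (t <= cmax).astype(int), "x": x, "m": m,
        })
        res, p = interaction_test(eps, "x", "m", weights=None)
        assert p < 0.01
        assert res.term("x:m")["coef"] == pytest.approx(0.5, abs=0.15)

    def test_constant_modifier_rejected(self, toy_pheno):
        eps = split_episodes(toy_pheno)
        eps["m"] = 1.0
        with pytest.raises(SurvivalError, match="vary"):
            interaction_test(eps, "height_cm", "m", weights=None)

    def test_duplicated_exposure_as_modifier_is_collinear(self):
        rng = np.random.default_rng(7)
        n = 200
        x = (rng.uniform(size=n) < 0.5).astype(float)
        eps = pd.DataFrame({
            "person": [f"P{i}" for i in range(n)],
            "family": [f"F{i}" for i in range(n)],
            "start": 0.0, "stop": rng.uniform(1, 5, n),
            "event": (rng.uniform(size=n) < 0.5).astype(int), "x": x,
        })
        eps["x2"] = x  # binary: x*x == x, fully collinear
        with pytest.raises(cox.CollinearityError):
            interaction_test(eps, "x", "x2", weights=None)


class TestSubtypes:
    def test_censoring_reassignment_matches_manual(self, toy_pheno):
        out = censor_other_class(toy_pheno.assign(
            histology=toy_pheno["histology"].map(
                {"serous": "serous", "endometrioid": "non-serous"})),
            "histology", "serous")
        # P2 (endometrioid case at 45) becomes a non-case censored at 45
        p2 = out.set_index("person").loc["P2"]
        assert p2["case"] == 0
        assert p2["age_end_followup"] == 45.0
        assert np.isnan(p2["age_ovca"])
        # serous cases P0, P5 untouched
        assert out.set_index("person").loc[["P0", "P5"], "case"].tolist() == [1, 1]

    def test_all_cases_one_class_equals_overall_fit(self, small_cohort):
        ph = small_cohort.phenotypes.copy()
        ph["histology"] = ph["histology"].where(ph["case"] == 0, "serous")
        ph["trait"] = small_cohort.latent["trait_true"].to_numpy()
        out = subtype_analysis(
            ph, "histology", {"serous": ["serous"], "other": ["other"]},
            "trait", ["gene"], incidence=None, weights=None)
        assert set(out["per_class"]) == {"serous"}
        assert out["p_het"] is None
        direct = fit_weighted_cox(split_episodes(ph), ["trait", "gene"],
                                  weights=None)
        got = out["per_class"]["serous"].term("trait")["coef"]
        assert got == pytest.approx(direct.term("trait")["coef"], abs=1e-10)

    def test_null_heterogeneity_rejection_near_alpha(self):
        rng = np.random.default_rng(8)
        n_rep, n = 200, 500
        rejections = 0
        for _ in range(n_rep):
            x = rng.normal(size=n)
            t = rng.exponential(np.exp(-0.3 * x))
            cmax = np.quantile(t, 0.6)
            case = t <= cmax
            ph = make_pheno(["BRCA1"] * n, np.minimum(t, cmax) + 20.0,
                            case.astype(int))
            ph["trait"] = x
            # random class labels: both classes share the same true effect
            ph["histology"] = np.where(rng.uniform(size=n) < 0.5, "a", "b")
            ph.loc[~case, "histology"] = None
            out = subtype_analysis(ph, "histology",
                                   {"a": ["a"], "b": ["b"]},
                                   "trait", [], incidence=None, weights=None)
            if out["p_het"] is not None and out["p_het"] < 0.05:
                rejections += 1
        assert 0.015 <= rejections / n_rep <= 0.105
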