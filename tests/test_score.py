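"""Tests of genetic-score construction and trait scaling."""

import numpy as np
import pandas as pd
import pytest

from carriermr.score import (ScoreError, align_alleles, build_raw_scores,
                             build_scores, cross_trait_check, fit_scaling,
                             load_snp_weights)


def make_panel(n, rng=None, info=None):
    rng = rng or np.random.default_rng(0)
    info = np.ones(n) if info is None else np.asarray(info, float)
    return pd.DataFrame({
        "rsid": [f"rs{i}" for i in range(n)],
        "chrom": ["1"] * n,
        "pos": np.arange(1, n + 1) * 1000,
        "effect_allele": ["A"] * n,
        "other_allele": ["C"] * n,
        "beta": rng.uniform(0.01, 0.1, n),
        "eaf": rng.uniform(0.1, 0.9, n),
        "info": info,
    })


def write_panel(df, path):
    df.to_csv(path, sep="\t", index=False)
    return path


class TestLoadSnpWeights:
    def test_quality_threshold_is_strictly_below(self, tmp_path):
        panel = make_panel(5, info=[0.9, 0.7, 0.49, 0.5, 0.3])
        p = write_panel(panel, tmp_path / "w.tsv")
        kept = load_snp_weights(p, min_quality=0.5)
        assert len(kept) == 3            # 0.49 and 0.3 dropped, 0.5 retained
        assert kept.attrs["n_dropped_quality"] == 2
        assert set(kept["rsid"]) == {"rs0", "rs1", "rs3"}

    def test_zero_threshold_retains_all(self, tmp_path):
        p = write_panel(make_panel(5, info=[0.9, 0.7, 0.49, 0.5, 0.3]),
                        tmp_path / "w.tsv")
        assert len(load_snp_weights(p, min_quality=0.0)) == 5

    def test_height_panel_count_preserved(self, tmp_path):
        # a height-panel-sized fixture (586 variants, all adequate quality)
        rng = np.random.default_rng(1)
        panel = make_panel(586, rng=rng,
                           info=rng.uniform(0.5, 1.0, 586).round(3))
        p = write_panel(panel, tmp_path / "w.tsv")
        assert len(load_snp_weights(p, min_quality=0.5)) == 586

    def test_duplicate_rsid_rejected(self, tmp_path):
        panel = make_panel(3)
        panel.loc[2, "rsid"] = "rs0"
        p = write_panel(panel, tmp_path / "w.tsv")
        with pytest.raises(ScoreError, match="duplicate"):
            load_snp_weights(p)

    def test_missing_column_named_in_error(self, tmp_path):
        panel = make_panel(3).drop(columns="eaf")
        p = write_panel(panel, tmp_path / "w.tsv")
        with pytest.raises(ScoreError, match="eaf"):
            load_snp_weights(p)


class TestBuildRawScores:
    def test_all_zero_dosages_score_zero(self):
        panel = make_panel(4)
        G = pd.DataFrame(0.0, index=["a", "b"], columns=panel["rsid"])
        assert (build_raw_scores(G, panel) == 0).all()

    def test_single_snp_direct_product(self):
        panel = make_panel(1)
        panel["beta"] = 0.05
        G = pd.DataFrame({"rs0": [2.0]}, index=["a"])
        assert build_raw_scores(G, panel).iloc[0] == pytest.approx(0.10)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        panel = make_panel(8, rng=rng)
        G = pd.DataFrame(rng.uniform(0, 2, (10, 8)),
                         index=[f"p{i}" for i in range(10)],
                         columns=panel["rsid"])
        scores = build_raw_scores(G, panel)
        for i, person in enumerate(G.index):
            expected = 0.0
            for j, rsid in enumerate(panel["rsid"]):
                expected += panel["beta"].iloc[j] * G.loc[person, rsid]
            assert scores[person] == pytest.approx(expected, abs=1e-12)

    def test_linear_in_panels_and_column_order_invariant(self):
        rng = np.random.default_rng(3)
        p1 = make_panel(5, rng=rng)
        p2 = make_panel(5, rng=rng)
        p2["rsid"] = [f"rs{i+5}" for i in range(5)]
        both = pd.concat([p1, p2], ignore_index=True)
        G = pd.DataFrame(rng.uniform(0, 2, (6, 10)),
                         columns=both["rsid"], index=range(6))
        s_both = build_raw_scores(G, both)
        s_sum = build_raw_scores(G, p1) + build_raw_scores(G, p2)
        assert np.allclose(s_both, s_sum, atol=1e-12)
        shuffled = G[rng.permutation(G.columns)]
        assert np.allclose(build_raw_scores(shuffled, both), s_both,
                           atol=1e-12)

    def test_missing_dosage_mean_imputed_as_2eaf(self):
        panel = make_panel(2)
        panel["beta"] = [0.1, 0.2]
        panel["eaf"] = [0.25, 0.5]
        G = pd.DataFrame({"rs0": [np.nan], "rs1": [1.0]}, index=["a"])
        # imputed dosage 2*0.25 = 0.5 -> 0.5*0.1 + 1*0.2
        assert build_raw_scores(G, panel).iloc[0] == pytest.approx(0.25)

    def test_absent_rsid_rejected(self):
        panel = make_panel(2)
        G = pd.DataFrame({"rs0": [1.0]}, index=["a"])
        with pytest.raises(ScoreError, match="rs1"):
            build_raw_scores(G, panel)


class TestAlleleAlignment:
    def base_panel(self):
        panel = make_panel(3)
        panel["effect_allele"] = ["A", "A", "G"]
        panel["other_allele"] = ["C", "G", "C"]
        panel["eaf"] = [0.2, 0.3, 0.25]
        return panel

    def test_match_swap_and_complement(self):
        panel = self.base_panel()
        ga = pd.DataFrame({
            "rsid": ["rs0", "rs1", "rs2"],
            "counted_allele": ["A", "G", "C"],   # same / swapped / complement
            "other_allele": ["C", "A", "G"],
        })
        aligned = align_alleles(panel, ga)
        assert aligned["flip"].tolist() == [False, True, True]
        G = pd.DataFrame([[1.0, 0.5, 2.0]], columns=panel["rsid"], index=["a"])
        s = build_raw_scores(G, aligned)
        expected = (panel["beta"].iloc[0] * 1.0
                    + panel["beta"].iloc[1] * 1.5
                    + panel["beta"].iloc[2] * 0.0)
        assert s.iloc[0] == pytest.approx(expected)

    def test_ambiguous_palindromic_rejected_only_at_mid_frequency(self):
        panel = make_panel(2)
        panel["effect_allele"] = ["A", "A"]
        panel["other_allele"] = ["T", "T"]
        panel["eaf"] = [0.5, 0.1]
        ga = pd.DataFrame({"rsid": ["rs0", "rs1"],
                           "counted_allele": ["A", "A"],
                           "other_allele": ["T", "T"]})
        with pytest.raises(ScoreError, match="rs0"):
            align_alleles(panel, ga)
        ok = align_alleles(panel.iloc[[1]], ga)
        assert ok["flip"].tolist() == [False]

    def test_mismatch_lists_rsids(self):
        panel = self.base_panel()
        ga = pd.DataFrame({"rsid": ["rs0", "rs1", "rs2"],
                           "counted_allele": ["A", "C", "G"],
                           "other_allele": ["C", "G", "C"]})
        with pytest.raises(ScoreError, match="rs1"):
            align_alleles(panel, ga)


class TestScaling:
    def test_identity_trait(self):
        raw = pd.Series([0.1, 0.5, 0.9, 1.3])
        m = fit_scaling(raw, raw, pd.Series([1, 1, 1, 1]))
        assert m.beta0 == pytest.approx(0.0, abs=1e-12)
        assert m.beta1 == pytest.approx(1.0, abs=1e-12)
        assert m.r2 == pytest.approx(1.0)

    def test_two_point_closed_form(self):
        raw = pd.Series([0.0, 1.0, 5.0])
        trait = pd.Series([160.0, 165.0, 999.0])
        non_case = pd.Series([1, 1, 0])  # the case row must be ignored
        with pytest.raises(ScoreError):
            fit_scaling(raw, trait, non_case)  # only 2 non-cases
        raw = pd.Series([0.0, 1.0, 2.0])
        trait = pd.Series([160.0, 165.0, 170.0])
        m = fit_scaling(raw, trait, pd.Series([1, 1, 1]))
        assert m.beta0 == pytest.approx(160.0, abs=1e-10)
        assert m.beta1 == pytest.approx(5.0, abs=1e-10)
        assert m.r2 == pytest.approx(1.0)

    def test_slope_recovery_with_noise(self):
        # generator slope 5.217 (the reported height scaling magnitude)
        rng = np.random.default_rng(4)
        n = 10_000
        raw = pd.Series(rng.normal(1.0, 0.3, n))
        trait = pd.Series(165.455 - 5.217 + 5.217 * raw + rng.normal(0, 6, n))
        m = fit_scaling(raw, trait, pd.Series(np.ones(n, int)))
        se = 6 / (0.3 * np.sqrt(n))
        assert abs(m.beta1 - 5.217) < 3 * se

    def test_scaled_score_regresses_with_unit_slope(self, small_cohort):
        c = small_cohort
        ph = c.phenotypes
        scores, model = build_scores(
            c.dosages, c.snp_weights,
            ph.set_index("person")["height_cm"],
            (ph.set_index("person")["case"] == 0),
        )
        mask = (ph.set_index("person")["case"] == 0) & \
            ph.set_index("person")["height_cm"].notna()
        refit = fit_scaling(scores.loc[mask.index[mask], "scaled_score"],
                            ph.set_index("person").loc[mask, "height_cm"],
                            pd.Series(1, index=mask.index[mask]))
        assert refit.beta1 == pytest.approx(1.0, abs=1e-8)
        assert refit.beta0 == pytest.approx(0.0, abs=1e-6)

    def test_zero_variance_scores_rejected(self):
        raw = pd.Series([1.0, 1.0, 1.0, 1.0])
        trait = pd.Series([160.0, 161.0, 162.0, 163.0])
        with pytest.raises(ScoreError, match="variance"):
            fit_scaling(raw, trait, pd.Series([1, 1, 1, 1]))


class TestCrossTrait:
    def test_independent_trait_null_slope(self):
        rng = np.random.default_rng(5)
        n = 10_000
        s = pd.Series(rng.normal(165, 2.5, n))
        t = pd.Series(rng.normal(25, 5, n))
        out = cross_trait_check(s, t)
        assert abs(out["slope"]) < 3 * out["se"]

    def test_identity_and_two_point(self):
        s = pd.Series([1.0, 2.0, 3.0])
        assert cross_trait_check(s, s)["slope"] == pytest.approx(1.0)
        t = pd.Series([160.0, 165.0, 170.0])
        out = cross_trait_check(pd.Series([0.0, 1.0, 2.0]), t)
        assert out["slope"] == pytest.approx(5.0, abs=1e-10)

    def test_constant_trait_rejected(self):
        with pytest.raises(ScoreError, match="constant"):
            cross_trait_check(pd.Series([1.0, 2.0, 3.0]),
                              pd.Series([5.0, 5.0, 5.0]))
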