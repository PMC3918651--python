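"""Tests of the correlation, interaction and stepwise-regression machinery."""

import numpy as np
import pandas as pd
import pytest

from admixpheno.phenotypes import derive
from admixpheno.simulate import SimulationConfig, simulate_phenotypes, simulate_true_pea
from admixpheno.stats import (
    adjusted_pearson,
    interaction_lrt,
    sex_difference_table,
    stepwise_forward,
    stratified_analysis,
)


class TestSexDifferences:
    def test_t_statistic_matches_closed_form(self):
        df = pd.DataFrame({"sex": ["F"] * 3 + ["M"] * 3,
                           "age": [1, 2, 3, 4, 5, 6]})
        out = sex_difference_table(df, continuous=["age"], categorical=[])
        row = out.iloc[0]
        # pooled SD 1, SE sqrt(2/3): t = -3/0.8165
        assert row["stat"] == pytest.approx(-3.674, abs=1e-3)

    def test_identical_groups_give_p_one(self):
        df = pd.DataFrame({"sex": ["F"] * 4 + ["M"] * 4,
                           "age": [1.0, 2.0, 3.0, 4.0] * 2})
        out = sex_difference_table(df, continuous=["age"], categorical=[])
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_single_sex_rejected(self):
        df = pd.DataFrame({"sex": ["F"] * 4, "age": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError):
            sex_difference_table(df, continuous=["age"], categorical=[])

    def test_generator_sex_gap_detected(self, derived_cohort):
        d, _ = derived_cohort
        out = sex_difference_table(d, continuous=["adiponectin"],
                                   categorical=[])
        row = out.iloc[0]
        assert row["p"] < 0.05 and row["mean_f"] > row["mean_m"]


class TestAdjustedPearson:
    def test_identity_gives_r_one(self):
        rng = np.random.default_rng(0)
        d = pd.DataFrame({"x": rng.normal(size=50)})
        d["y"] = d["x"]
        d["age"] = rng.normal(size=50)
        d["sex"] = np.where(rng.random(50) < 0.5, "F", "M")
        res = adjusted_pearson("x", "y", d)
        assert res.r == pytest.approx(1.0)

    def test_no_adjusters_equals_plain_pearson(self):
        rng = np.random.default_rng(1)
        d = pd.DataFrame({"x": rng.normal(size=80), "y": rng.normal(size=80)})
        res = adjusted_pearson("x", "y", d, adjusters=())
        assert res.r == pytest.approx(np.corrcoef(d["x"], d["y"])[0, 1],
                                      abs=1e-12)

    def test_matches_inverse_correlation_matrix_oracle(self):
        """Residual correlation equals the textbook partial correlation."""
        rng = np.random.default_rng(2)
        n = 300
        a = rng.normal(size=n)
        d = pd.DataFrame({
            "age": a,
            "x": 0.5 * a + rng.normal(size=n),
        })
        d["y"] = 0.3 * a - 0.4 * d["x"] + rng.normal(size=n)
        res = adjusted_pearson("x", "y", d, adjusters=("age",))
        R = np.corrcoef(np.column_stack([d["x"], d["y"], d["age"]]).T)
        P = np.linalg.inv(R)
        partial = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
        assert res.r == pytest.approx(partial, abs=1e-10)

    def test_null_correlation_small_at_large_n(self):
        rng = np.random.default_rng(3)
        n = 10_000
        a = rng.normal(size=n)
        d = pd.DataFrame({"age": a,
                          "x": a + rng.normal(size=n),
                          "y": a + rng.normal(size=n)})
        res = adjusted_pearson("x", "y", d, adjusters=("age",))
        assert abs(res.r) < 0.03

    def test_sign_structure_on_generator_defaults(self, derived_cohort):
        d, _ = derived_cohort
        assert adjusted_pearson("log_adiponectin", "homa_ir", d).r < 0
        assert adjusted_pearson("log_adiponectin", "hdl", d).r > 0
        assert adjusted_pearson("log_adiponectin", "pea", d).r > 0


class TestInteractionLrt:
    @staticmethod
    def frame(n=400, seed=0, gamma=0.0):
        rng = np.random.default_rng(seed)
        d = pd.DataFrame({"pea": rng.beta(4.67, 23.47, n),
                          "m": rng.normal(size=n),
                          "c": rng.normal(size=n),
                          "sex": "F"})
        d["y"] = (1 + 0.5 * d["pea"] + 0.3 * d["m"] + 0.2 * d["c"]
                  + gamma * d["pea"] * d["m"] + rng.normal(0, 0.5, n))
        return d

    def test_zero_variance_interaction_gives_zero_statistic(self):
        d = self.frame()
        d["m"] = 0.0  # constant modifier x exposure product
        with pytest.raises(ValueError, match="constant"):
            interaction_lrt("y", "pea", "m", ["c"], d)
        # non-constant modifier but constant product column
        d2 = self.frame()
        d2["m"] = np.where(d2["pea"] > 0, 1.0 / d2["pea"], 1.0)
        res = interaction_lrt("y", "pea", "m", ["c"], d2)
        assert res.lrt_stat == 0.0 and res.p == 1.0

    def test_affine_rescaling_invariance(self):
        d = self.frame(seed=4, gamma=1.0)
        r1 = interaction_lrt("y", "pea", "m", ["c"], d)
        d2 = d.copy()
        d2["c"] = 100.0 * d2["c"] - 7.0
        r2 = interaction_lrt("y", "pea", "m", ["c"], d2)
        assert r1.lrt_stat == pytest.approx(r2.lrt_stat, abs=1e-8)

    def test_rank_deficient_design_reported(self):
        d = self.frame(seed=5)
        d["m"] = 2.0 * d["pea"] + 1.0
        d["c"] = d["pea"] * d["m"]  # duplicates the interaction column
        with pytest.raises(ValueError, match="collinear"):
            interaction_lrt("y", "pea", "m", ["c"], d)

    def test_detects_effect_modification_with_power_above_nominal(self):
        """IR-stratum contrast (0.74 vs 0) is detected well above the 5%
        null rate; absolute power at these effect sizes is moderate."""
        cfg = SimulationConfig(beta_pea_nonobese=None, beta_pea_obese=None)
        hits = 0
        R = 60
        for i in range(R):
            s = simulate_true_pea(cfg.n_individuals, seed=40_000 + 2 * i)
            tab, _ = simulate_phenotypes(s, cfg, seed=40_001 + 2 * i)
            tab["pea"] = s
            d = derive(tab, glucose_units="mg/dL")
            d["ir01"] = (d["insulin_resistant"] == 1).astype(float)
            res = interaction_lrt("log_adiponectin", "pea", "ir01",
                                  ["age", "sex_male", "bmi", "waist", "hdl"],
                                  d)
            hits += res.p <= 0.05
        assert hits / R >= 0.15


class TestStepwise:
    def test_empty_candidates_returns_forced_model(self):
        rng = np.random.default_rng(6)
        d = pd.DataFrame({"pea": rng.normal(size=60)})
        d["y"] = 0.5 * d["pea"] + rng.normal(size=60)
        res = stepwise_forward("y", d, [], forced=("pea",))
        assert res.selected_terms == ("pea",)

    def test_exact_tie_breaks_by_candidate_order(self):
        rng = np.random.default_rng(7)
        d = pd.DataFrame({"a": rng.normal(size=100)})
        d["b"] = d["a"]                      # identical predictor
        d["y"] = d["a"] + rng.normal(0, 0.5, 100)
        res = stepwise_forward("y", d, ["b", "a"])
        assert res.selected_terms[0] == "b"

    def test_selection_independent_of_order_without_ties(self):
        rng = np.random.default_rng(8)
        n = 500
        d = pd.DataFrame({c: rng.normal(size=n) for c in "abc"})
        d["y"] = 1.0 * d["a"] + 0.5 * d["b"] + rng.normal(size=n)
        r1 = stepwise_forward("y", d, ["a", "b", "c"])
        r2 = stepwise_forward("y", d, ["c", "b", "a"])
        assert set(r1.selected_terms) == set(r2.selected_terms)

    def test_strong_candidate_enters_first(self):
        """Candidate with partial R^2 ~ 0.2 at n=700 wins the first step."""
        for i in range(25):
            rng = np.random.default_rng(100 + i)
            n = 700
            d = pd.DataFrame({"signal": rng.normal(size=n),
                              "n1": rng.normal(size=n),
                              "n2": rng.normal(size=n)})
            d["y"] = 0.5 * d["signal"] + rng.normal(size=n)
            res = stepwise_forward("y", d, ["n1", "signal", "n2"])
            assert res.selected_terms[0] == "signal"

    def test_unselected_focus_term_still_reported(self):
        rng = np.random.default_rng(19)
        n = 200
        d = pd.DataFrame({"pea": rng.normal(size=n),
                          "c": rng.normal(size=n)})
        d["y"] = 0.8 * d["c"] + rng.normal(size=n)
        res = stepwise_forward("y", d, ["c"], focus="pea")
        t = res.term("pea")
        assert not t.selected
        assert np.isfinite(t.p) and np.isfinite(t.beta)


class TestStratified:
    def test_small_strata_skipped(self, derived_cohort):
        d, _ = derived_cohort
        out = stratified_analysis(d.head(4), min_n=50,
                                  sensitivity_no_diabetes=False)
        assert out == []

    def test_defaults_produce_expected_strata(self, derived_cohort):
        d, _ = derived_cohort
        res = stratified_analysis(d)
        labels = [r.stratum for r in res]
        assert labels == ["non-obese", "obese", "non-IR", "IR", "no-diabetes"]
        nonir = next(r for r in res if r.stratum == "non-IR")
        # unmeasured HOMA-IR individuals belong to the insulin-sensitive
        # stratum, so its size exceeds the measured complement
        assert nonir.n >= (d["insulin_resistant"] == 0).sum()
        for r in res:
            assert 0 <= r.r2 <= 1
            assert any(t.name == "pea" for t in r.terms)
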