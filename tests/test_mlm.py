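"""Multilevel model machinery: nesting, LRT, simple slopes, recovery."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

import effortnirs as en
from effortnirs.mlm import (
    INTERACTION,
    MAIN_EFFECT,
    UNCONDITIONAL,
    HbDiffModel,
    ModelSpec,
    compare_nested,
    nested_hierarchy,
    simple_slopes,
)

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)

NO_COVARIATE = ModelSpec(program=True, subregion=True, interaction=True)


@pytest.fixture(scope="module")
def hierarchy(trial_table):
    return nested_hierarchy(trial_table)


class TestModelSpec:
    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError):
            ModelSpec(interaction=True)

    def test_nesting_relation(self):
        assert UNCONDITIONAL.is_nested_in(MAIN_EFFECT)
        assert MAIN_EFFECT.is_nested_in(INTERACTION)
        assert not INTERACTION.is_nested_in(MAIN_EFFECT)

    def test_missing_columns_error(self):
        with pytest.raises(ValueError, match="missing"):
            HbDiffModel(pd.DataFrame({"hbdiff": [1.0]}), UNCONDITIONAL)


class TestFit:
    def test_zero_variance_outcome_gives_zero_slopes(self):
        tbl = en.simulate_trial_table(
            n_participants=4, n_trials=3, seed=0, residual_sd_um=0.0,
            participant_sd_um=0.0, effects_um={"left_lateral": 0.0},
            handedness_effect_um=0.0, intercept_um=5.0,
        )
        res = HbDiffModel(tbl, NO_COVARIATE).fit()
        assert res.fe_params.iloc[0] == pytest.approx(5.0)
        assert np.all(res.fe_params.iloc[1:] == 0.0)

    def test_balanced_design_matches_ols(self):
        # in a balanced design the mixed-model fixed effects equal OLS exactly
        tbl = en.simulate_trial_table(n_participants=8, n_trials=4, seed=2)
        res = HbDiffModel(tbl, NO_COVARIATE).fit()
        ols = smf.ols(NO_COVARIATE.formula("hbdiff"), data=tbl).fit()
        np.testing.assert_allclose(res.fe_params.values, ols.params.values, atol=1e-6)

    def test_program_effect_recovery_over_seeds(self):
        # paper-like size: 26 participants x 12 trials x 2 programs x 3 regions
        term = "C(condition, Treatment('standard'))[T.dnn]"
        ests = []
        for s in range(20):
            tbl = en.simulate_trial_table(seed=s)
            ests.append(float(HbDiffModel(tbl, NO_COVARIATE).fit().fe_params[term]))
        assert np.mean(ests) == pytest.approx(-19.0, rel=0.15)

    def test_missing_rows_tolerated(self, trial_table):
        tbl = trial_table.copy()
        tbl.loc[tbl.sample(frac=0.1, random_state=0).index, "hbdiff"] = np.nan
        res = HbDiffModel(tbl, NO_COVARIATE).fit()
        assert res.n_obs == tbl.hbdiff.notna().sum()

    def test_df_separates_between_and_within_terms(self, hierarchy):
        res = hierarchy["results"]["interaction"]
        fe = res.fixed_effects()
        assert fe.loc["handedness[right]", "df"] <= res.n_groups
        assert fe.loc["program[dnn]", "df"] > 1000

    def test_aic_identity(self, hierarchy):
        for res in hierarchy["results"].values():
            assert res.aic == pytest.approx(2 * res.k_params - 2 * res.llf)

    def test_summary_renders(self, hierarchy):
        s = hierarchy["results"]["interaction"].summary()
        assert "program[dnn]" in s and "AIC" in s


class TestNestedComparison:
    def test_lrt_is_twice_delta_loglik(self, hierarchy):
        res = hierarchy["results"]
        for small, big, key in [
            ("unconditional", "main_effect", "main_vs_unconditional"),
            ("main_effect", "interaction", "interaction_vs_main"),
        ]:
            cmp = hierarchy["comparisons"][key]
            assert cmp["chi2"] == pytest.approx(2 * (res[big].llf - res[small].llf), abs=1e-8)
            assert cmp["chi2"] >= 0.0

    def test_main_vs_interaction_df_is_four(self, hierarchy):
        assert hierarchy["comparisons"]["interaction_vs_main"]["df"] == 4

    def test_identical_models_give_null_comparison(self, trial_table):
        res = HbDiffModel(trial_table, MAIN_EFFECT).fit()
        cmp = compare_nested(res, res)
        assert cmp["chi2"] == 0.0 and cmp["p"] == 1.0 and cmp["df"] == 0

    def test_non_nested_error(self, trial_table):
        a = HbDiffModel(trial_table, ModelSpec(effort=True)).fit()
        b = HbDiffModel(trial_table, ModelSpec(program=True)).fit()
        with pytest.raises(ValueError, match="nested"):
            compare_nested(a, b)

    def test_different_rows_error(self, trial_table):
        a = HbDiffModel(trial_table, UNCONDITIONAL).fit()
        b = HbDiffModel(trial_table.iloc[: len(trial_table) // 2], MAIN_EFFECT).fit()
        with pytest.raises(ValueError, match="observation"):
            compare_nested(a, b)


class TestSimpleSlopes:
    def test_refit_equals_linear_combination(self, hierarchy):
        res = hierarchy["results"]["interaction"]
        a = simple_slopes(res, "refit").set_index("subregion")
        b = simple_slopes(res, "contrast").set_index("subregion")
        np.testing.assert_allclose(a["estimate"], b["estimate"], atol=1e-6)
        np.testing.assert_allclose(a["se"], b["se"], atol=1e-6)

    def test_requires_interaction_model(self, trial_table):
        res = HbDiffModel(trial_table, MAIN_EFFECT).fit()
        with pytest.raises(ValueError, match="interaction"):
            simple_slopes(res)

    def test_uniform_effect_gives_equal_slopes(self):
        tbl = en.simulate_trial_table(
            seed=4, effects_um={"left_lateral": -19.0, "lower_medial": -19.0, "right_lateral": -19.0}
        )
        res = HbDiffModel(tbl, NO_COVARIATE).fit()
        sl = simple_slopes(res).set_index("subregion")
        spread = sl["estimate"].max() - sl["estimate"].min()
        assert spread < 3 * sl["se"].max()

    def test_localised_effect_detected_in_left_lateral(self):
        tbl = en.simulate_trial_table(seed=5)
        res = HbDiffModel(tbl, NO_COVARIATE).fit()
        sl = simple_slopes(res).set_index("subregion")
        assert sl.loc["left_lateral", "p"] < 0.05
        assert sl.loc["left_lateral", "estimate"] < 0


class TestBrainBehaviour:
    def test_uncorrelated_effort_gives_null_slope(self):
        tbl = en.simulate_trial_table(seed=6, effort_slope_um=0.0)
        out = en.brain_behaviour_model(tbl, correct_only=True)
        se = float(out["result"].bse["effort"])
        assert abs(out["slope"]) < 3 * se

    def test_programmed_slope_recovered(self):
        # no program effect here: a condition effect on both effort and HbDiff
        # would confound the effort slope, which is a property of the design,
        # not of the estimator under test
        ests = []
        for s in range(5):
            tbl = en.simulate_trial_table(
                seed=100 + s, effort_slope_um=8.0, effects_um={"left_lateral": 0.0}
            )
            ests.append(en.brain_behaviour_model(tbl, correct_only=True)["slope"])
        assert np.mean(ests) == pytest.approx(8.0, abs=2.5)

    def test_correct_only_is_subset(self, trial_table):
        all_rows = en.brain_behaviour_model(trial_table, correct_only=False)
        correct_rows = en.brain_behaviour_model(trial_table, correct_only=True)
        assert correct_rows["result"].n_obs < all_rows["result"].n_obs

    def test_no_correct_trials_errors(self, trial_table):
        tbl = trial_table.copy()
        tbl["correct"] = False
        with pytest.raises(ValueError, match="correct"):
            en.brain_behaviour_model(tbl, correct_only=True)
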