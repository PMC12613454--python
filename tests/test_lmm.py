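"""Mixed-model fitting, contrasts and reporting."""

import numpy as np
import pandas as pd
import pytest

from hapticlearn.lmm import (
    MotorLearningModel,
    bonferroni,
    build_design,
    default_contrast_plan,
    fit_lmm,
    model_compare,
    model_spec,
    percent_change_from_delta,
    report_effects,
)


def _cond(group="Control", stage="BL", task="mn", tc=0.0, loc=0.0, s=0.0):
    return {"Group": group, "Task": task, "Stage": stage, "sIndex": s,
            "TC_c": tc, "LOC_c": loc}


class TestModelSpec:
    def test_known_ids(self):
        assert model_spec("M1.1").response == "log10_abs_error"
        assert model_spec("M1.2").response == "log10_int_force"
        assert model_spec("M2").tasks == ("mn",)

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError):
            model_spec("M3")
        with pytest.raises(ValueError):
            model_spec("M2", question="happiness")


class TestBuildDesign:
    def test_m11_column_count_matches_hand_expansion(self, small_study):
        """1 + 1 + 2 + 2 + 3 (traits, sIndex) + 2 + 2 + (2+2+1)*2 trait
        interactions + 4 Task:Stage + 1 + 2 triple = 30 columns."""
        _, data = small_study
        y, X, vc, d = build_design(data.trials, model_spec("M1.1"))
        assert X.shape[1] == 30
        assert set(vc.columns) == {"ID", "wall_key"}

    def test_m12_adds_loc_interaction_columns(self, small_study):
        _, data = small_study
        _, X, _, _ = build_design(data.trials, model_spec("M1.2"))
        assert X.shape[1] == 33

    def test_single_task_collapses_with_warning(self, small_study):
        _, data = small_study
        sub = data.trials[data.trials.Task == "mn"]
        with pytest.warns(UserWarning, match="single level"):
            _, X, _, _ = build_design(sub, model_spec("M1.1"))
        assert X.shape[1] < 30

    def test_traits_centered_in_design(self, small_study):
        _, data = small_study
        shifted = data.trials.assign(TC_c=data.trials.TC_c + 0.3)
        _, _, _, d = build_design(shifted, model_spec("M1.1"))
        assert abs(d.drop_duplicates("ID").TC_c.mean()) < 1e-12

    def test_missing_columns_listed(self):
        with pytest.raises(ValueError, match="abs_error"):
            build_design(pd.DataFrame({"ID": [1]}), model_spec("M1.1"))

    def test_t1_walls_get_distinct_random_levels(self, small_study):
        _, data = small_study
        _, _, vc, d = build_design(data.trials, model_spec("M1.1"))
        t1_keys = set(vc.loc[d.Task == "t1", "wall_key"])
        mn_keys = set(vc.loc[d.Task == "mn", "wall_key"])
        assert t1_keys.isdisjoint(mn_keys)


class TestFitLmm:
    def test_balanced_anova_closed_form(self):
        """REML variance components match the balanced one-way ANOVA
        estimators to 1e-6."""
        rng = np.random.default_rng(0)
        n_g, n_per = 30, 10
        a = rng.normal(0, 0.5, n_g)
        y = 1.2 + np.repeat(a, n_per) + rng.normal(0, 0.8, n_g * n_per)
        df = pd.DataFrame({"y": y, "g": np.repeat(np.arange(n_g), n_per)})
        ybar = df.groupby("g")["y"].mean().values
        mse = ((y - np.repeat(ybar, n_per)) ** 2).sum() / (n_g * (n_per - 1))
        msb = n_per * ((ybar - y.mean()) ** 2).sum() / (n_g - 1)
        res = fit_lmm("y ~ 1", df, vc_formula={"g": "0 + C(g)"}, refine=True)
        assert abs(res.scale - mse) < 1e-6
        assert abs(res.vcomp[0] - (msb - mse) / n_per) < 1e-6
        assert res.fe_params.iloc[0] == pytest.approx(y.mean(), abs=1e-8)

    def test_zero_variance_degenerates_to_ols(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        y = 0.5 + 0.8 * x + rng.normal(0, 1, 200)
        df = pd.DataFrame({"y": y, "x": x, "g": np.repeat(np.arange(20), 10)})
        res = fit_lmm("y ~ x", df, vc_formula={"g": "0 + C(g)"},
                      zero_variance=True)
        X = np.column_stack([np.ones(200), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.max(np.abs(np.asarray(res.fe_params) - beta)) < 1e-8

    def test_parameter_recovery_coverage(self):
        """Data simulated from a known crossed-intercept model: the fixed
        effect lands inside its 95% CI in >=90% of 50 replicates."""
        b1 = 0.7
        hits = 0
        for rep in range(50):
            rng = np.random.default_rng(100 + rep)
            n_id, n_w = 12, 15
            ids = np.repeat(np.arange(n_id), n_w)
            walls = np.tile(np.arange(n_w), n_id)
            x = rng.normal(size=n_id * n_w)
            y = (0.3 + b1 * x + rng.normal(0, 0.3, n_id)[ids]
                 + rng.normal(0, 0.2, n_w)[walls]
                 + rng.normal(0, 0.5, n_id * n_w))
            df = pd.DataFrame({"y": y, "x": x, "ID": ids, "w": walls})
            res = fit_lmm("y ~ x", df,
                          vc_formula={"ID": "0 + C(ID)", "w": "0 + C(w)"})
            se = np.sqrt(np.asarray(res.cov_params())[1, 1])
            b = res.fe_params.iloc[1]
            hits += (b - 1.96 * se) <= b1 <= (b + 1.96 * se)
        assert hits >= 45


class TestPercentChange:
    @pytest.fixture(scope="class")
    def m11(self, small_study):
        _, data = small_study
        return MotorLearningModel(data.trials, "M1.1").fit()

    def test_reporting_convention(self):
        assert percent_change_from_delta(0.0) == 0.0
        # the printed convention: a log10 ratio of 0.62 is a 38 % reduction
        assert percent_change_from_delta(np.log10(0.62)) == pytest.approx(38.0)
        assert percent_change_from_delta(-0.2076) == pytest.approx(38.0, abs=0.05)

    def test_identical_conditions_zero_change(self, m11):
        eff = m11.percent_change(_cond(), _cond())
        assert eff.percent_change == 0.0
        assert eff.ci_low <= 0.0 <= eff.ci_high

    def test_monotone_ci_transform(self, m11):
        eff = m11.percent_change(_cond(), _cond(stage="STR"))
        assert eff.ci_low < eff.percent_change < eff.ci_high

    def test_missing_condition_field_listed(self, m11):
        bad = _cond()
        del bad["LOC_c"]
        with pytest.raises(ValueError, match="LOC_c"):
            m11.percent_change(bad, _cond(stage="STR"))

    def test_self_difference_of_changes_is_zero(self, m11):
        pair = (_cond(), _cond(stage="STR"))
        eff = m11.difference_of_changes(pair, pair)
        assert eff.delta_log10 == 0.0

    def test_stage_permutation_destroys_effect(self, small_study):
        """Shuffling stage labels within participants removes the learning
        signal: the corrected BL->STR contrast is non-significant."""
        _, data = small_study
        df = data.trials.copy()
        rng = np.random.default_rng(0)
        df["Stage"] = df.groupby("ID")["Stage"].transform(
            lambda s: s.sample(frac=1, random_state=rng.integers(2**31)).values
        )
        res = MotorLearningModel(df, "M1.1").fit()
        eff = res.percent_change(_cond(), _cond(stage="STR"), family_size=16)
        assert eff.p_corrected > 0.05


class TestBonferroni:
    def test_values(self):
        assert bonferroni(0.01, 10) == pytest.approx(0.1)
        assert bonferroni(0.2, 10) == 1.0
        assert bonferroni(0.3, 1) == pytest.approx(0.3)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(1.5, 2)


class TestModelCompareAndReport:
    def test_identical_models_zero_delta(self, small_study):
        _, data = small_study
        r = MotorLearningModel(data.trials, "M1.1").fit()
        tab = model_compare([r, r])
        assert tab.delta_aic.tolist() == [0.0, 0.0]

    def test_mismatched_datasets_rejected(self, small_study):
        _, data = small_study
        r1 = MotorLearningModel(data.trials, "M1.1").fit()
        r2 = MotorLearningModel(data.trials, "M1.2").fit()
        with pytest.raises(ValueError):
            model_compare([r1, r2])

    def test_null_extra_term_costs_about_two_aic(self):
        """Adding a pure-noise regressor moves AIC by at most ~2 and BIC
        prefers the simpler model."""
        rng = np.random.default_rng(3)
        n_id = 20
        ids = np.repeat(np.arange(n_id), 20)
        x = rng.normal(size=len(ids))
        z = rng.normal(size=len(ids))  # no effect
        y = 0.2 + 0.5 * x + rng.normal(0, 0.4, n_id)[ids] + rng.normal(0, 0.6, len(ids))
        df = pd.DataFrame({"y": y, "x": x, "z": z, "g": ids})
        base = fit_lmm("y ~ x", df, vc_formula={"g": "0 + C(g)"}, reml=False)
        extra = fit_lmm("y ~ x + z", df, vc_formula={"g": "0 + C(g)"}, reml=False)
        aic = lambda r, k: -2 * r.llf + 2 * k
        bic = lambda r, k: -2 * r.llf + np.log(len(df)) * k
        k_b, k_e = 4, 5  # fe + vc + residual
        d_aic = aic(extra, k_e) - aic(base, k_b)
        assert -4.0 < d_aic <= 2.1
        assert bic(extra, k_e) > bic(base, k_b)

    def test_default_plan_row_counts(self, small_study):
        """Hand enumeration: M1.1 has LOC bars only for Control
        (2 stages x (5 + 3)); M1.2 has them for both groups."""
        assert len(default_contrast_plan("M1.1")) == 16
        assert len(default_contrast_plan("M1.2")) == 20
        _, data = small_study
        r = MotorLearningModel(data.trials, "M1.1").fit()
        tab = report_effects(r)
        assert len(tab) == 16
        assert tab.p_corrected.between(0, 1).all()
        assert (tab.ci_low <= tab.percent_change).all()
        assert (tab.percent_change <= tab.ci_high).all()


class TestM2:
    def test_fit_and_contrast(self, small_study):
        _, data = small_study
        model = MotorLearningModel(data.trials, "M2", hri=data.hri,
                                   question="frustration")
        res = model.fit()
        cond = {"Stage": "BL", "AC_c": 0.0, "FS_c": 0.0, "TC_c": 0.0,
                "LOC_c": 0.0, "HRIQ_c": 0.0}
        eff = res.percent_change(cond, {**cond, "Stage": "LTR"})
        assert np.isfinite(eff.percent_change)

    def test_requires_hri_table(self, small_study):
        _, data = small_study
        with pytest.raises(ValueError, match="HRI"):
            MotorLearningModel(data.trials, "M2", hri=None)
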