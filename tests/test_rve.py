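"""Correlated-effects RVE: reductions, small-sample inference, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.meta_analysis import combine_effects

from cbmeta.effect_size import BehavioralRecord, es_table_to_frame, g_repeated_measures
from cbmeta.rve import (
    design_from_moderators,
    egger_rve,
    fit_rve,
    influence_diagnostics,
    sensitivity_grid,
    wald_omnibus,
)


class TestReductions:
    def test_single_study_single_es_returns_it_exactly(self):
        with pytest.warns(UserWarning, match="fewer than 2 studies"):
            fit = fit_rve(np.array([0.5]), np.array([0.01]), np.array(["a"]))
        assert fit.coefficients[0] == pytest.approx(0.5, abs=1e-14)

    def test_equal_variance_singletons_give_unweighted_mean(self):
        # equal k and vbar make all weights equal regardless of tau^2
        fit = fit_rve(np.array([0.2, 0.4, 0.9]), np.full(3, 0.04),
                      np.array(["a", "b", "c"]))
        assert fit.coefficients[0] == pytest.approx(0.5, abs=1e-14)

    def test_one_es_per_study_equals_dersimonian_laird(self):
        # with one ES per study the CE moment estimator reduces to the
        # classic DerSimonian-Laird random-effects estimate
        rng = np.random.default_rng(0)
        y = rng.normal(0.5, 0.3, 12)
        v = rng.uniform(0.01, 0.1, 12)
        fit = fit_rve(y, v, np.arange(12))
        oracle = combine_effects(y, v, method_re="dl")
        assert fit.tau2 == pytest.approx(oracle.tau2, rel=1e-10)
        assert fit.coefficients[0] == pytest.approx(
            float(oracle.summary_frame().loc["random effect", "eff"]), rel=1e-10)

    def test_rho_does_not_move_the_equal_variance_estimate(self):
        y = np.array([0.2, 0.4, 0.9])
        v = np.full(3, 0.04)
        fits = [fit_rve(y, v, np.array(["a", "b", "c"]), rho=r)
                for r in (0.0, 0.2, 0.5, 0.8, 0.95)]
        ests = [f.coefficients[0] for f in fits]
        assert np.ptp(ests) < 1e-12


class TestWeighting:
    def _toy(self):
        rng = np.random.default_rng(1)
        study = np.repeat([f"s{j}" for j in range(8)], [1, 2, 3, 1, 4, 2, 1, 2])
        y = rng.normal(0.5, 0.3, len(study))
        v = rng.uniform(0.02, 0.1, len(study))
        return y, v, study

    def test_weights_equal_within_study_and_scale_as_ce(self):
        y, v, study = self._toy()
        fit = fit_rve(y, v, study)
        df = pd.DataFrame({"study": study, "w": fit.weights, "v": v})
        for sid, grp in df.groupby("study"):
            assert np.ptp(grp["w"]) < 1e-14
            k = len(grp)
            expected = 1.0 / (k * (grp["v"].mean() + fit.tau2))
            assert grp["w"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_inference_invariant_to_row_order(self):
        y, v, study = self._toy()
        fit = fit_rve(y, v, study)
        perm = np.random.default_rng(2).permutation(len(y))
        fit_p = fit_rve(y[perm], v[perm], study[perm])
        assert fit_p.coefficients[0] == pytest.approx(fit.coefficients[0], rel=1e-12)
        assert fit_p.robust_se[0] == pytest.approx(fit.robust_se[0], rel=1e-10)
        assert fit_p.df[0] == pytest.approx(fit.df[0], rel=1e-8)

    def test_rank_deficient_design_names_aliased_columns(self):
        y, v, study = self._toy()
        X = np.c_[np.ones(len(y)), np.arange(len(y)), 2.0 * np.arange(len(y))]
        with pytest.raises(ValueError, match="x2"):
            fit_rve(y, v, study, X=X)


class TestWald:
    def _fit(self):
        rng = np.random.default_rng(3)
        study = np.repeat([f"s{j}" for j in range(15)], 2)
        x = rng.integers(0, 2, len(study)).astype(float)
        y = rng.normal(0.4 + 0.3 * x, 0.2)
        v = rng.uniform(0.02, 0.08, len(study))
        return fit_rve(y, v, study, X=np.c_[np.ones(len(y)), x],
                       labels=["intercept", "group"])

    def test_single_coefficient_f_equals_squared_t(self):
        fit = self._fit()
        res = wald_omnibus(fit, [1])
        assert res.F == pytest.approx(fit.t_values[1] ** 2, rel=1e-10)
        assert res.df2 == pytest.approx(fit.df[1], rel=1e-10)
        assert res.p == pytest.approx(fit.p_values[1], rel=1e-8)

    def test_zero_estimate_gives_zero_statistic(self):
        y = np.array([0.5, 0.5, 0.5, 0.5])
        v = np.full(4, 0.04)
        x = np.array([0.0, 1.0, 0.0, 1.0])
        fit = fit_rve(y, v, np.array(["a", "b", "c", "d"]),
                      X=np.c_[np.ones(4), x])
        res = wald_omnibus(fit, [1])
        assert res.F == pytest.approx(0.0, abs=1e-20)

    def test_intercept_in_subset_warns(self):
        fit = self._fit()
        with pytest.warns(UserWarning, match="intercept"):
            wald_omnibus(fit, [0, 1])

    def test_null_three_level_moderator_rejects_at_nominal_rate(self):
        # omnibus calibration under a true null
        rng = np.random.default_rng(42)
        n_rep, rejections = 150, 0
        for _ in range(n_rep):
            study = np.repeat([f"s{j}" for j in range(25)], 2)
            n = len(study)
            level = rng.integers(0, 3, n)
            X = np.c_[np.ones(n), level == 1, level == 2].astype(float)
            if np.linalg.matrix_rank(X) < 3:
                continue
            theta = rng.normal(0.5, 0.15, 25)
            y = theta[np.repeat(np.arange(25), 2)] + rng.normal(0, 0.15, n)
            v = np.full(n, 0.15**2)
            fit = fit_rve(y, v, study, X=X)
            rejections += wald_omnibus(fit, [1, 2]).p < 0.05
        rate = rejections / n_rep
        assert 0.005 <= rate <= 0.11


class TestModeratorRecovery:
    def test_group_difference_is_recovered_with_nominal_coverage(self):
        rng = np.random.default_rng(7)
        delta, covered, n_rep = 0.3, 0, 60
        for _ in range(n_rep):
            study = np.repeat([f"s{j}" for j in range(30)], 2)
            n = len(study)
            x = rng.integers(0, 2, n).astype(float)
            theta = rng.normal(0.4, 0.15, 30)
            y = theta[np.repeat(np.arange(30), 2)] + delta * x + rng.normal(0, 0.2, n)
            v = np.full(n, 0.04)
            fit = fit_rve(y, v, study, X=np.c_[np.ones(n), x])
            lo, hi = fit.ci95[1]
            covered += lo <= delta <= hi
        assert covered / n_rep >= 0.85


class TestEgger:
    def test_constant_effect_sizes_give_zero_slope(self):
        v = np.linspace(0.01, 0.1, 8)
        fit = egger_rve(np.full(8, 0.5), v, np.arange(8))
        assert fit.coefficients[1] == pytest.approx(0.0, abs=1e-10)

    def test_slope_invariant_to_constant_shift_of_g(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(0.01, 0.1, 15)
        y = rng.normal(0.4, 0.2, 15)
        a = egger_rve(y, v, np.arange(15))
        b = egger_rve(y + 1.0, v, np.arange(15))
        assert b.coefficients[1] == pytest.approx(a.coefficients[1], rel=1e-8)
        assert b.coefficients[0] == pytest.approx(a.coefficients[0] + 1.0, rel=1e-8)

    def test_selection_toward_large_noisy_effects_yields_positive_slope(self):
        # publication-bias injection: high-variance estimates only survive
        # when they come out large
        rng = np.random.default_rng(11)
        y, v = [], []
        while len(y) < 100:
            vi = rng.uniform(0.005, 0.2)
            yi = rng.normal(0.2, np.sqrt(vi + 0.01))
            if yi / np.sqrt(vi) > 2.0 or rng.random() < 0.05:
                y.append(yi)
                v.append(vi)
        fit = egger_rve(np.array(y), np.array(v), np.arange(len(y)))
        assert fit.coefficients[1] > 0
        assert fit.p_values[1] < 0.05

    def test_constant_standard_errors_are_an_error(self):
        with pytest.raises(ValueError, match="identical"):
            egger_rve(np.array([0.1, 0.2, 0.3]), np.full(3, 0.04), np.arange(3))


class TestInfluence:
    def test_identical_effect_sizes_flag_nothing(self):
        table = influence_diagnostics(np.full(8, 0.5), np.full(8, 0.04))
        assert not table["influential"].any()

    def test_grossly_displaced_case_is_flagged(self):
        y = np.full(10, 0.5)
        y[3] = 0.5 + 10 * 0.2
        table = influence_diagnostics(y, np.full(10, 0.04))
        assert bool(table.loc[3, "influential"])
        assert table.loc[table.index != 3, "influential"].sum() == 0

    def test_removing_a_non_flagged_case_barely_moves_the_estimate(self):
        rng = np.random.default_rng(9)
        y = rng.normal(0.5, 0.1, 12)
        v = np.full(12, 0.04)
        table = influence_diagnostics(y, v)
        ok = table.loc[~table["influential"], "index"].iloc[0]
        fit_all = fit_rve(y, v, np.arange(12))
        keep = np.delete(np.arange(12), ok)
        fit_del = fit_rve(y[keep], v[keep], np.arange(11))
        assert abs(fit_del.coefficients[0] - fit_all.coefficients[0]) \
            < fit_all.robust_se[0]

    def test_too_few_cases_is_an_error(self):
        with pytest.raises(ValueError):
            influence_diagnostics(np.array([0.1, 0.2]), np.array([0.01, 0.01]))


class TestSensitivity:
    def _records(self):
        out = []
        for i in range(8):
            out.append(BehavioralRecord(
                study_id=f"s{i // 2}", experiment_id=f"e{i}", n=25,
                mean_I=600.0 + 5 * i, sd_I=100.0, mean_C=550.0, sd_C=100.0,
                r=0.8 if i % 2 == 0 else None))
        return out

    def test_rho_grid_leaves_intercept_nearly_unchanged(self):
        records = [g_repeated_measures(r, 0.8) for r in self._records()]
        frame = es_table_to_frame(records)
        table = sensitivity_grid(frame, "rho", [0.2, 0.5, 0.8, 0.9])
        assert np.ptp(table["intercept"]) < 1e-4

    def test_r_grid_keeps_estimates_stable_while_per_es_se_shrinks(self):
        # with near-equal condition SDs, d barely depends on the assumed r,
        # so the grid moves the per-effect-size SE (Var_d ~ 1-r) but leaves
        # the pooled point estimate essentially unchanged
        from cbmeta.effect_size import records_from_frame, g_repeated_measures
        from cbmeta.synthetic import BehavSimConfig, gen_behavioral_dataset

        table, _ = gen_behavioral_dataset(BehavSimConfig(
            n_studies=40, prob_r_observed=1.0, seed=21))
        records = records_from_frame(table)
        grid = sensitivity_grid(records, "r", [0.0, 0.4, 0.8])
        fixed = grid[grid["grid"] != "real"]
        assert np.ptp(fixed["intercept"]) < 0.05
        assert np.ptp(fixed["robust_se"]) < 0.005
        mean_var = [np.mean([g_repeated_measures(rec, r).var_g for rec in records])
                    for r in (0.0, 0.4, 0.8)]
        assert mean_var[0] > mean_var[1] > mean_var[2]

    def test_single_point_grid_equals_direct_fit(self):
        records = [g_repeated_measures(r, 0.8) for r in self._records()]
        frame = es_table_to_frame(records)
        table = sensitivity_grid(frame, "rho", [0.8])
        direct = fit_rve(frame["g"].to_numpy(), frame["var_g"].to_numpy(),
                         frame["study_id"].to_numpy(), rho=0.8)
        assert table["intercept"].iloc[0] == pytest.approx(
            direct.coefficients[0], rel=1e-14)

    def test_out_of_range_grid_is_an_error(self):
        with pytest.raises(ValueError, match=r"\(-1, 1\)"):
            sensitivity_grid(self._records(), "r", [0.5, 1.5])


def test_design_from_moderators_reference_coding():
    frame = pd.DataFrame({"material": ["color_word", "emotional", "other",
                                       "color_word"]})
    X, names = design_from_moderators(frame, ["material"],
                                      {"material": "color_word"})
    assert names == ["intercept", "material[emotional]", "material[other]"]
    np.testing.assert_allclose(X[:, 0], 1.0)
    np.testing.assert_allclose(X[1], [1.0, 1.0, 0.0])
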