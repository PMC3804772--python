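"""LIE fitting, prediction, leave-one-out and model statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from noscabind import (EnergyComponents, LIECoefficients, LIESimConfig,
                       LIETrainingTable, PUBLISHED_COEFFICIENTS,
                       anova_oneway_from_summary, fit_lie, loo_predictions,
                       pearson_r2, predict_dg, simulate_lie_table)
from noscabind.lie import SingularDesignError, TableSizeError

from conftest import coefficient_standard_errors, normal_equations_fit


def make_table(X, y, ids=None):
    ids = ids or [f"c{i}" for i in range(len(X))]
    rows = tuple((EnergyComponents(ids[i], *X[i]), float(y[i]))
                 for i in range(len(X)))
    return LIETrainingTable(rows=rows)


class TestPredict:
    @pytest.mark.parametrize("energy, expected", [
        ((-62.62, 76.07, 1.287), -6.189),   # 6f
        ((-57.50, 7.551, 0.776), -4.923),   # 6j
    ])
    def test_published_coefficients_reproduce_printed_values(self, energy, expected):
        e = EnergyComponents("x", *energy)
        assert predict_dg(PUBLISHED_COEFFICIENTS, e) == pytest.approx(
            expected, abs=5e-4)

    def test_zero_energy_zero_intercept_gives_zero(self):
        e = EnergyComponents("z", 0.0, 0.0, 0.0)
        assert predict_dg(LIECoefficients(3.0, -2.0, 0.5), e) == 0.0

    def test_designed_set_predicted_column_within_rounding(self, table2_records):
        # the printed column is regenerated by the rounded coefficients
        for rec in table2_records:
            got = predict_dg(PUBLISHED_COEFFICIENTS, rec.energy)
            assert got == pytest.approx(rec.dg_predicted, abs=2e-3), rec.compound_id


class TestFit:
    def test_noiseless_exact_model_recovery(self, table1_records):
        truth = LIECoefficients(0.072, -0.006, -0.951)
        X = np.array([r.energy.as_vector() for r in table1_records])
        y = X @ np.array(truth.as_array()[:3])
        rep = fit_lie(make_table(X, y))
        for got, want in zip(rep.coefficients.as_array()[:3], truth.as_array()[:3]):
            assert got == pytest.approx(want, abs=1e-10)
        assert rep.rmse == pytest.approx(0.0, abs=1e-10)

    def test_training_fit_matches_independent_normal_equations(self, table1_training):
        """Fit on the printed training columns agrees with the hand-solved
        3x3 normal equations; coefficients land near the published triple."""
        X = table1_training.design_matrix
        y = table1_training.dg_experimental
        oracle = normal_equations_fit(X, y)
        rep = fit_lie(table1_training)
        assert np.allclose(rep.coefficients.as_array()[:3], oracle, atol=1e-8)
        # near, but not asserted equal to, the printed rounded values
        assert abs(rep.coefficients.alpha - 0.072) < 0.01
        assert abs(rep.coefficients.beta - (-0.006)) < 0.01
        assert abs(rep.coefficients.gamma - (-0.951)) < 0.05
        assert 0.0 <= rep.r2_train <= 1.0

    def test_noisy_recovery_within_three_standard_errors(self):
        truth = LIECoefficients(0.1, -0.01, -0.8)
        table = simulate_lie_table(LIESimConfig(
            coeffs_true=truth, n_compounds=50, noise_sd=0.05, seed=7))
        rep = fit_lie(table)
        se = coefficient_standard_errors(table.design_matrix,
                                         table.dg_experimental)
        for got, want, s in zip(rep.coefficients.as_array()[:3],
                                truth.as_array()[:3], se):
            assert abs(got - want) < 3 * s

    @given(st.integers(min_value=0, max_value=500))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_fit_matches_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        X = rng.normal(size=(n, 3)) * [10.0, 30.0, 0.5] + [-55.0, 60.0, 1.0]
        y = X @ [0.08, -0.005, -0.9] + rng.normal(0, 0.1, size=n)
        rep = fit_lie(make_table(X, y))
        oracle = normal_equations_fit(X, y)
        assert np.allclose(rep.coefficients.as_array()[:3], oracle, atol=1e-8)

    def test_intercept_flag_fits_constant_term(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 3))
        y = X @ [0.1, -0.2, 0.3] + 1.5
        rep = fit_lie(make_table(X, y), include_intercept=True)
        assert rep.coefficients.intercept == pytest.approx(1.5, abs=1e-8)

    def test_rank_deficient_design_names_columns(self):
        X = np.array([[1.0, 2.0, 2.0], [2.0, 1.0, 1.0],
                      [3.0, 4.0, 4.0], [4.0, 3.0, 3.0], [5.0, 5.0, 5.0]])
        with pytest.raises(SingularDesignError, match="u_elec"):
            fit_lie(make_table(X, X @ [1.0, 1.0, 0.0]))

    def test_too_few_rows(self):
        X = np.eye(3)
        with pytest.raises(TableSizeError):
            fit_lie(make_table(X, np.ones(3)))

    def test_fit_then_predict_reproduces_noiseless_training_rows(self):
        table = simulate_lie_table(LIESimConfig(
            coeffs_true=LIECoefficients(0.05, -0.02, -1.2), n_compounds=10,
            noise_sd=0.0, seed=11))
        rep = fit_lie(table)
        for energy, dg in table.rows:
            assert predict_dg(rep.coefficients, energy) == pytest.approx(
                dg, abs=1e-10)


class TestLeaveOneOut:
    def test_noiseless_loo_equals_full_fit(self):
        table = simulate_lie_table(LIESimConfig(
            coeffs_true=LIECoefficients(0.072, -0.006, -0.951),
            n_compounds=8, noise_sd=0.0, seed=2))
        rep = fit_lie(table)
        loo = loo_predictions(table)
        for energy, _ in table.rows:
            assert loo[energy.compound_id] == pytest.approx(
                predict_dg(rep.coefficients, energy), abs=1e-9)

    def test_training_set_loo_produces_seven_values(self, table1_training):
        loo = loo_predictions(table1_training)
        assert len(loo) == 7
        assert set(loo) == set(table1_training.compound_ids)

    def test_outlier_loo_residual_exceeds_full_fit_residual(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(5, 3))
        y = X @ [0.1, -0.2, 0.5]
        y[2] += 10.0  # gross outlier
        table = make_table(X, y)
        rep = fit_lie(table)
        loo = loo_predictions(table)
        full_resid = abs(rep.residuals[2])
        loo_resid = abs(y[2] - loo["c2"])
        assert loo_resid > full_resid


class TestPearsonR2:
    def test_training_table_correlations(self, table1_records):
        pred = [r.dg_predicted for r in table1_records]
        exp = [r.dg_experimental for r in table1_records]
        glide = [r.glide_xp_score for r in table1_records]
        assert pearson_r2(pred, exp) == pytest.approx(0.780, abs=1e-3)
        assert pearson_r2(glide, exp) == pytest.approx(0.615, abs=1e-3)

    def test_perfect_affine_relation(self):
        x = [1.0, 2.0, 4.0, 7.0]
        y = [2 * v + 3 for v in x]
        assert pearson_r2(x, y) == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(min_value=0, max_value=100),
           st.floats(min_value=-5, max_value=5).filter(lambda s: abs(s) > 1e-3),
           st.floats(min_value=-10, max_value=10))
    @settings(max_examples=50, derandomize=True)
    def test_symmetry_and_affine_invariance(self, seed, slope, shift):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        base = pearson_r2(x, y)
        assert pearson_r2(y, x) == pytest.approx(base, rel=1e-12)
        assert pearson_r2(slope * x + shift, y) == pytest.approx(base, rel=1e-9)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAnovaFromSummary:
    def test_equal_means_give_zero_f(self):
        res = anova_oneway_from_summary([1.0, 1.0], [1.0, 1.0], [5, 5])
        assert res.f_statistic == 0.0

    def test_two_group_hand_expansion(self):
        # means 0 and 1, sds 1, n=10 each: SSB = 10*0.25*2 = 5, df_b = 1;
        # SSW = 9 + 9 = 18, df_w = 18 -> F = 5 / 1 = 5
        res = anova_oneway_from_summary([0.0, 1.0], [1.0, 1.0], [10, 10])
        assert res.f_statistic == pytest.approx(5.0, rel=1e-12)
        assert (res.df_between, res.df_within) == (1, 18)

    def test_matches_scipy_on_reconstructed_groups(self):
        from scipy.stats import f_oneway
        rng = np.random.default_rng(0)
        groups = [rng.normal(loc, 1.0, size=6) for loc in (0.0, 0.5, 2.0)]
        res = anova_oneway_from_summary(
            [g.mean() for g in groups], [g.std(ddof=1) for g in groups],
            [len(g) for g in groups])
        assert res.f_statistic == pytest.approx(
            f_oneway(*groups).statistic, rel=1e-10)

    def test_designed_set_kd_summary_f_is_finite(self, table2_records):
        kd = [(r.kd_mean, r.kd_sd) for r in table2_records if r.kd_mean]
        res = anova_oneway_from_summary([m for m, _ in kd], [s for _, s in kd],
                                        [3] * len(kd))
        assert np.isfinite(res.f_statistic) and res.f_statistic > 0

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            anova_oneway_from_summary([2.0, 2.0], [0.0, 0.0], [3, 3])
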