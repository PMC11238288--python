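"""OLS surface fitting, prediction, ANOVA bookkeeping and the R² family."""

import numpy as np
import pytest

from rsmpso import (
    GroundTruth,
    PROCESS_FACTORS,
    QuadraticSurface,
    ResponseTable,
    anova_table,
    build_design_matrix,
    build_ccd,
    fit_ols,
    fitted_values,
    generate_ccd_dataset,
    predict,
    r2_family,
)
from rsmpso.surfaces import SingularFitError, UndefinedRSquaredError


class TestDesignMatrix:
    def test_center_row_second_order(self, chl_table):
        X = build_design_matrix(chl_table.design, order=2)
        center_rows = X[np.all(chl_table.design.coded_matrix == 0, axis=1)]
        assert np.allclose(center_rows, [1] + [0] * 9)

    def test_axial_row_second_order(self, factors):
        design = build_ccd(factors, alpha=2, n_center=6)
        X = build_design_matrix(design, order=2)
        i = next(
            j for j, p in enumerate(design.points) if p.coded == (-2.0, 0.0, 0.0)
        )
        assert np.allclose(X[i], [1, -2, 0, 0, 4, 0, 0, 0, 0, 0])

    def test_full_rank(self, chl_table):
        X = build_design_matrix(chl_table.design, order=2)
        assert np.linalg.matrix_rank(X) == 10

    def test_first_order_columns(self, chl_table):
        X = build_design_matrix(chl_table.design, order=1)
        assert X.shape == (20, 4)
        assert np.allclose(X[:, 0], 1)


class TestFit:
    def test_center_prediction_matches_reported(self, chl_surface):
        # six replicated center runs share one prediction; agreement with the
        # published 7.53 is limited by the 2-dp rounding of the input means
        assert chl_surface.evaluate_coded([0.0, 0.0, 0.0]) == pytest.approx(
            7.53, abs=0.02
        )

    def test_interaction_coefficient_equals_contrast_oracle(self, chl_table, chl_surface):
        """Orthogonality makes OLS b23 equal the factorial contrast sum(x2*x3*y)/8."""
        x = chl_table.design.coded_matrix
        z = x[:, 1] * x[:, 2]
        contrast = float(z @ chl_table.y / (z @ z))
        assert chl_surface.interaction[2] == pytest.approx(contrast, rel=1e-10)
        assert contrast == pytest.approx(0.59375, abs=1e-9)

    def test_linear_and_interaction_terms_equal_contrasts(self, aa_table, aa_surface):
        x = aa_table.design.coded_matrix
        cols = {
            "x1": (x[:, 0], aa_surface.linear[0]),
            "x2": (x[:, 1], aa_surface.linear[1]),
            "x3": (x[:, 2], aa_surface.linear[2]),
            "x1x2": (x[:, 0] * x[:, 1], aa_surface.interaction[0]),
            "x1x3": (x[:, 0] * x[:, 2], aa_surface.interaction[1]),
            "x2x3": (x[:, 1] * x[:, 2], aa_surface.interaction[2]),
        }
        for name, (z, beta) in cols.items():
            assert beta == pytest.approx(float(z @ aa_table.y / (z @ z)), rel=1e-9), name

    def test_zero_noise_recovers_truth(self, true_surface, zero_noise_table):
        fit = fit_ols(zero_noise_table, order=2)
        assert np.allclose(fit.coefficients, true_surface.coefficients, atol=1e-8)

    def test_refit_on_fitted_values_is_idempotent(self, chl_table, chl_surface):
        clean = ResponseTable(
            design=chl_table.design,
            response_name="refit",
            y=fitted_values(chl_table, chl_surface),
        )
        again = fit_ols(clean, order=2)
        assert np.allclose(again.coefficients, chl_surface.coefficients, atol=1e-10)

    def test_singular_design_raises(self, factors):
        design = build_ccd(factors, alpha=2, n_center=6)
        # duplicate a single factorial point 20 times -> rank deficient
        from rsmpso.design import design_from_natural

        nat = np.tile(design.natural_matrix[0], (20, 1))
        broken = design_from_natural(nat, factors)
        table = ResponseTable(design=broken, response_name="x", y=np.ones(20))
        with pytest.raises(SingularFitError):
            fit_ols(table, order=2)

    def test_first_order_fit_is_affine(self, chl_table):
        mlr = fit_ols(chl_table, order=1)
        # prediction at the coded origin is the grand mean for this balanced design
        assert mlr.evaluate_coded([0.0, 0.0, 0.0]) == pytest.approx(
            chl_table.y.mean(), rel=1e-10
        )


class TestPredict:
    @pytest.mark.parametrize(
        "fixture, point, expected, tol",
        [
            ("chl_surface", (8, 80, 40), 7.33, 0.02),
            ("aa_surface", (4, 80, 50), 121.70, 0.1),
        ],
    )
    def test_reported_prediction_values(self, request, fixture, point, expected, tol):
        surface = request.getfixturevalue(fixture)
        assert predict(surface, point, PROCESS_FACTORS) == pytest.approx(
            expected, abs=tol
        )

    def test_center_prediction_is_intercept(self, true_surface):
        assert predict(true_surface, (8, 80, 50), PROCESS_FACTORS) == pytest.approx(
            true_surface.b0
        )


class TestAnova:
    def test_reported_interaction_and_pure_error_ss(self, chl_table, chl_surface):
        report = anova_table(chl_table, chl_surface)
        assert report.row("X2*X3").adj_ss == pytest.approx(2.82, abs=0.005)
        assert report.row("pure-error").adj_ss == pytest.approx(0.05, abs=0.005)

    def test_ss_additivity(self, chl_table, chl_surface):
        report = anova_table(chl_table, chl_surface)
        model, error, total = (
            report.row("model").adj_ss,
            report.row("error").adj_ss,
            report.row("total").adj_ss,
        )
        assert model + error == pytest.approx(total, rel=1e-8)
        lof, pe = report.row("lack-of-fit").adj_ss, report.row("pure-error").adj_ss
        assert lof + pe == pytest.approx(error, rel=1e-8)

    def test_df_bookkeeping(self, aa_table, aa_surface):
        report = anova_table(aa_table, aa_surface)
        assert report.row("model").df + report.row("error").df == report.row("total").df
        assert report.row("total").df == 19
        assert (
            report.row("lack-of-fit").df + report.row("pure-error").df
            == report.row("error").df
        )

    def test_group_ss_equals_member_sum_for_orthogonal_groups(self, chl_table, chl_surface):
        """Linear and interaction contrasts are orthogonal, so their group
        adjusted SS is the sum of the single-df terms.  (Square columns are
        mutually correlated; their group SS is legitimately non-additive.)"""
        report = anova_table(chl_table, chl_surface)
        for group, members in [
            ("linear", ["X1", "X2", "X3"]),
            ("two-way", ["X1*X2", "X1*X3", "X2*X3"]),
        ]:
            total = sum(report.row(m).adj_ss for m in members)
            assert report.row(group).adj_ss == pytest.approx(total, rel=1e-6)

    def test_reported_group_ss(self, chl_table, chl_surface):
        report = anova_table(chl_table, chl_surface)
        assert report.row("linear").adj_ss == pytest.approx(3.44, abs=0.005)
        assert report.row("square").adj_ss == pytest.approx(8.20, abs=0.005)
        assert report.row("two-way").adj_ss == pytest.approx(3.30, abs=0.005)

    def test_zero_noise_anova(self, zero_noise_table):
        fit = fit_ols(zero_noise_table, order=2)
        report = anova_table(zero_noise_table, fit)
        assert report.row("error").adj_ss == pytest.approx(0.0, abs=1e-16)
        assert report.r2 == pytest.approx(1.0)

    def test_anova_requires_quadratic(self, chl_table):
        mlr = fit_ols(chl_table, order=1)
        with pytest.raises(TypeError):
            anova_table(chl_table, mlr)

    def test_additivity_on_random_synthetic_tables(self, true_surface, factors):
        rng = np.random.default_rng(42)
        for rep in range(20):
            truth = GroundTruth(
                surface=true_surface, noise_sd=float(rng.uniform(0.01, 0.5)),
                seed=int(rng.integers(0, 2**31)),
            )
            table = generate_ccd_dataset(truth, factors)
            report = anova_table(table, fit_ols(table, order=2))
            assert report.row("model").adj_ss + report.row("error").adj_ss == (
                pytest.approx(report.row("total").adj_ss, rel=1e-8)
            )


class TestR2Family:
    def test_reported_r2_values(self, chl_table, chl_surface):
        fam = r2_family(chl_table, chl_surface)
        assert 100 * fam["r2"] == pytest.approx(99.35, abs=0.01)
        assert 100 * fam["pred_r2"] == pytest.approx(97.26, abs=0.01)
        assert 100 * fam["adj_r2"] == pytest.approx(98.77, abs=0.01)

    def test_ordering(self, aa_table, aa_surface):
        fam = r2_family(aa_table, aa_surface)
        assert fam["pred_r2"] <= fam["adj_r2"] <= fam["r2"] <= 1

    def test_perfect_fit(self, zero_noise_table):
        fit = fit_ols(zero_noise_table, order=2)
        fam = r2_family(zero_noise_table, fit)
        assert fam["r2"] == pytest.approx(1.0)
        assert fam["adj_r2"] == pytest.approx(1.0)
        assert fam["pred_r2"] == pytest.approx(1.0)

    def test_zero_variance_response_raises(self, factors):
        design = build_ccd(factors, alpha=2, n_center=6)
        table = ResponseTable(design=design, response_name="flat", y=np.full(20, 3.0))
        surface = QuadraticSurface(
            b0=3.0, linear=np.zeros(3), quadratic=np.zeros(3), interaction=np.zeros(3)
        )
        with pytest.raises(UndefinedRSquaredError):
            r2_family(table, surface)


def test_parameter_recovery_error_shrinks_with_noise(true_surface, factors):
    """Coefficient RMSE is monotone in the noise level (averaged over replicates)."""
    from rsmpso import recovery_experiment

    rmses = []
    for sd in (0.05, 0.1, 0.2):
        truth = GroundTruth(surface=true_surface, noise_sd=sd, seed=7)
        res = recovery_experiment(truth, factors, n_reps=100)
        rmses.append(res["rmse"].mean())
    assert rmses[0] < rmses[1] < rmses[2]
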