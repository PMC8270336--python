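"""Quadratic response-surface fit, ANOVA and optimum location.

Frozen expected values for the packaged 29-run experiment were computed
with the statsmodels OLS oracle in ``test_against_statsmodels_oracle``;
published 2-dp values are asserted at the coarser printed precision.
"""

import itertools

import numpy as np
import pytest

from flavopt.design import build_bbd, code_point
from flavopt.errors import SingularDesignError
from flavopt.rsm import (
    QuadraticModel,
    absolute_error,
    anova,
    design_matrix,
    fit_quadratic,
    optimize_on_cube,
    r_squared,
    term_labels,
)
from flavopt.synthetic_data import DEFAULT_QUADRATIC_COEF, SyntheticSpec, gen_bbd_response


def _grid_max(model, n=41):
    """Dense-grid oracle: exhaustive evaluation on an n^4 lattice."""
    axis = np.linspace(-1, 1, n)
    best = -np.inf
    for a in axis:  # chunk over the first axis to bound memory
        pts = np.array(list(itertools.product([a], axis, axis, axis)))
        best = max(best, float(model.predict(pts).max()))
    return best


class TestFitQuadratic:
    def test_reproduces_published_coefficients(self, extraction_model):
        m = extraction_model
        assert m.b0 == pytest.approx(10.30, abs=5e-3)
        assert m.b_lin[0] == pytest.approx(0.81, abs=5e-3)
        assert m.b_lin[1] == pytest.approx(0.40, abs=5e-3)
        assert m.b_lin[2] == pytest.approx(-1.47, abs=5.1e-3)  # -1.4650 prints as -1.47
        assert m.b_lin[3] == pytest.approx(1.15, abs=5e-3)
        # interactions AB, AC, AD, BC, BD, CD
        assert np.allclose(
            m.b_int, [-1.43, -1.53, -0.048, 0.20, -1.23, -0.59], atol=5.1e-3
        )
        assert np.allclose(m.b_quad, [-0.68, -1.55, -3.50, -3.03], atol=5.1e-3)

    def test_noiseless_recovery_exact(self):
        spec = SyntheticSpec(kind="bbd", noise_sd=0.0, seed=0)
        design = gen_bbd_response(spec)
        model = fit_quadratic(design)
        assert np.allclose(model.coefficients, DEFAULT_QUADRATIC_COEF, atol=1e-10)

    def test_linear_coefficient_contrast_identity(self, toy_factors):
        # on a complete BBD, b_i = (sum y at x_i=+1 - sum y at x_i=-1) / 12
        rng = np.random.default_rng(42)
        design = build_bbd(toy_factors, n_center=5).with_response(
            rng.normal(5, 2, size=29)
        )
        model = fit_quadratic(design)
        for i in range(4):
            plus = design.response[design.coded[:, i] == 1].sum()
            minus = design.response[design.coded[:, i] == -1].sum()
            assert model.b_lin[i] == pytest.approx((plus - minus) / 12, abs=1e-10)

    def test_rank_deficiency_names_columns(self, toy_factors):
        # duplicate a single edge run 29 times -> massively aliased
        coded = np.tile(np.array([1.0, 1.0, 0.0, 0.0]), (29, 1))
        from flavopt.design import DesignTable

        design = DesignTable(
            factors=toy_factors, coded=coded, response=np.ones(29)
        )
        with pytest.raises(SingularDesignError) as err:
            fit_quadratic(design)
        assert err.value.aliased

    def test_too_few_runs_rejected(self, toy_bbd):
        resp = np.full(29, np.nan)
        resp[:10] = 1.0
        with pytest.raises(SingularDesignError):
            fit_quadratic(toy_bbd.with_response(resp))

    def test_against_statsmodels_oracle(self, extraction_design, extraction_model):
        sm = pytest.importorskip("statsmodels.api")
        X = design_matrix(extraction_design.coded)
        fit = sm.OLS(extraction_design.response, X).fit()
        assert np.allclose(extraction_model.coefficients, fit.params, atol=1e-8)


class TestPredict:
    def test_origin_gives_intercept(self, extraction_model):
        assert extraction_model.predict(np.zeros(4)) == pytest.approx(
            extraction_model.b0
        )

    def test_published_optimum_value(self, extraction_model):
        pred = extraction_model.predict_natural([40.0, 50.9, 8.82, 148.87])
        assert pred == pytest.approx(11.07, abs=5e-3)

    def test_matches_manual_expansion(self, extraction_model):
        rng = np.random.default_rng(7)
        x = rng.uniform(-1, 1, size=4)
        m = extraction_model
        manual = m.b0
        manual += sum(m.b_lin[i] * x[i] for i in range(4))
        manual += sum(
            m.b_int[k] * x[i] * x[j]
            for k, (i, j) in enumerate(itertools.combinations(range(4), 2))
        )
        manual += sum(m.b_quad[i] * x[i] ** 2 for i in range(4))
        assert m.predict(x) == pytest.approx(manual, abs=1e-12)

    def test_extrapolation_flagged(self, extraction_model):
        assert extraction_model.is_extrapolating([2.0, 0, 0, 0])
        assert not extraction_model.is_extrapolating([1.0, 0, 0, 0])

    def test_json_round_trip(self, tmp_path, extraction_model):
        path = tmp_path / "model.json"
        extraction_model.to_json(path)
        back = QuadraticModel.from_json(path)
        assert np.allclose(back.coefficients, extraction_model.coefficients)


class TestAnova:
    def test_published_table(self, extraction_anova):
        tab = extraction_anova
        assert tab.row("Model").f == pytest.approx(42.61, abs=5e-3)
        assert tab.row("A").ss == pytest.approx(7.79, abs=5e-3)
        assert tab.row("B").ss == pytest.approx(1.88, abs=5e-3)
        assert tab.row("C").ss == pytest.approx(25.75, abs=5.1e-3)
        assert tab.row("D").ss == pytest.approx(15.96, abs=5e-3)
        assert tab.row("AB").ss == pytest.approx(8.12, abs=5e-3)
        assert tab.row("AC").ss == pytest.approx(9.36, abs=5e-3)
        assert tab.row("Pure Error").ss == pytest.approx(0.78, abs=5e-3)
        assert tab.row("Lack of Fit").f == pytest.approx(1.98, abs=5e-3)
        assert tab.row("C").f == pytest.approx(78.15, abs=0.05)
        assert tab.row("D").f == pytest.approx(48.43, abs=0.05)

    def test_additivity(self, extraction_anova):
        tab = extraction_anova
        ss_parts = tab.row("Model").ss + tab.row("Residual").ss
        assert ss_parts == pytest.approx(tab.ss_total, rel=1e-8)
        assert tab.row("Lack of Fit").ss + tab.row("Pure Error").ss == pytest.approx(
            tab.row("Residual").ss, rel=1e-8
        )
        df_parts = tab.row("Model").df + tab.row("Residual").df
        assert df_parts == tab.df_total
        assert tab.row("Lack of Fit").df + tab.row("Pure Error").df == tab.row(
            "Residual"
        ).df

    def test_additivity_on_synthetic_fits(self):
        for seed in range(5):
            design = gen_bbd_response(
                SyntheticSpec(kind="bbd", noise_sd=0.5, seed=seed)
            )
            model = fit_quadratic(design)
            tab = anova(model, design)
            assert tab.row("Model").ss + tab.row("Residual").ss == pytest.approx(
                tab.ss_total, rel=1e-8
            )

    def test_noiseless_residual_zero(self):
        design = gen_bbd_response(SyntheticSpec(kind="bbd", noise_sd=0.0, seed=1))
        model = fit_quadratic(design)
        tab = anova(model, design)
        assert tab.row("Residual").ss == pytest.approx(0.0, abs=1e-16)
        assert r_squared(model, design)[0] == pytest.approx(1.0)

    def test_linear_partial_ss_contrast_identity(self, toy_factors):
        # partial SS of a linear term on a complete BBD = (sum x_i y)^2 / 12
        rng = np.random.default_rng(11)
        design = build_bbd(toy_factors, n_center=5).with_response(
            rng.normal(size=29)
        )
        model = fit_quadratic(design)
        tab = anova(model, design)
        for i, letter in enumerate("ABCD"):
            contrast = float(design.coded[:, i] @ design.response)
            assert tab.row(letter).ss == pytest.approx(contrast**2 / 12, abs=1e-10)

    def test_no_replicates_marks_lof_unavailable(self, toy_factors):
        design = build_bbd(toy_factors, n_center=1).with_response(
            np.random.default_rng(3).normal(size=25)
        )
        model = fit_quadratic(design)
        tab = anova(model, design)
        assert tab.row("Lack of Fit").ss is None
        assert tab.row("Pure Error").ss is None

    def test_against_statsmodels_type3(self, extraction_design, extraction_anova):
        """Cross-check partial SS against statsmodels' Type-III ANOVA."""
        import pandas as pd
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        d = pd.DataFrame(extraction_design.coded, columns=list("ABCD"))
        d["y"] = extraction_design.response
        fit = smf.ols(
            "y ~ A + B + C + D + A:B + A:C + A:D + B:C + B:D + C:D"
            " + I(A**2) + I(B**2) + I(C**2) + I(D**2)",
            data=d,
        ).fit()
        tab3 = anova_lm(fit, typ=3)
        for letter in "ABCD":
            assert extraction_anova.row(letter).ss == pytest.approx(
                tab3.loc[letter, "sum_sq"], abs=1e-8
            )


class TestRSquared:
    def test_published_value(self, extraction_model, extraction_design):
        r2, adj = r_squared(extraction_model, extraction_design)
        assert r2 == pytest.approx(0.9771, abs=5e-4)
        assert 0 < adj < r2

    def test_identity_both_ways(self, extraction_model, extraction_design):
        r2, _ = r_squared(extraction_model, extraction_design)
        y = extraction_design.response
        resid = y - extraction_model.predict(extraction_design.coded)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        assert r2 == pytest.approx((ss_tot - ss_res) / ss_tot, abs=1e-12)

    def test_constant_response_is_nan(self, toy_bbd):
        design = toy_bbd.with_response(np.full(29, 3.0))
        model = fit_quadratic(design)
        r2, adj = r_squared(model, design)
        assert np.isnan(r2) and np.isnan(adj)


class TestOptimizeOnCube:
    def test_beats_published_maximum(self, extraction_model):
        res = optimize_on_cube(extraction_model)
        assert res.predicted >= 11.06
        assert np.all(np.abs(res.coded) <= 1 + 1e-9)

    def test_agrees_with_grid_oracle(self, extraction_model):
        res = optimize_on_cube(extraction_model)
        assert res.predicted >= _grid_max(extraction_model) - 1e-4

    def test_interior_vertex_recovered(self, toy_factors):
        # concave separable paraboloid with known interior argmax
        target = np.array([0.3, -0.2, 0.5, -0.4])
        beta = np.zeros(15)
        beta[0] = 1.0
        beta[11:15] = -1.0
        beta[1:5] = -2 * beta[11:15] * target
        model = QuadraticModel.from_coefficients(beta, toy_factors)
        res = optimize_on_cube(model)
        assert np.allclose(res.coded, target, atol=1e-6)

    def test_flat_ridge_tie_breaks_to_smallest_norm(self, toy_factors):
        model = QuadraticModel.from_coefficients(np.zeros(15), toy_factors)
        res = optimize_on_cube(model)
        assert np.linalg.norm(res.coded) == pytest.approx(0.0, abs=1e-6)


class TestAbsoluteError:
    def test_published_validation_row(self):
        assert absolute_error(11.0688, 10.5571) == pytest.approx(0.5117, abs=1e-12)

    def test_equal_inputs_zero(self):
        assert absolute_error(5.0, 5.0) == 0.0

    def test_symmetry(self):
        assert absolute_error(2.0, 7.5) == absolute_error(7.5, 2.0)


class TestCoefficientRecovery:
    def test_mean_absolute_linear_error_under_noise(self):
        # 200 seeded designs, noise sd 0.3: mean |error| on linear terms < 0.2
        errs = []
        for seed in range(200):
            design = gen_bbd_response(
                SyntheticSpec(kind="bbd", noise_sd=0.3, seed=seed)
            )
            model = fit_quadratic(design)
            errs.append(np.abs(model.b_lin - DEFAULT_QUADRATIC_COEF[1:5]))
        assert float(np.mean(errs)) < 0.2
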