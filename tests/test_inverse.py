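"""Damped least-squares estimator: steps, convergence, covariance, statistics."""

import numpy as np
import pytest

from thermofit.forward import (
    ChillingConditions,
    CylinderGeometry,
    ThermalParameters,
    center_curve,
)
from thermofit.inverse import (
    CenterCoolingRegressor,
    ObservationSeries,
    covariance_report,
    fit,
    fit_statistics,
    normal_equations,
    report_from_covariance,
    residuals,
    sensitivity_matrix,
    to_dimensionless,
)
from thermofit.synthgen import (
    CARROT_ALPHA,
    CARROT_H_REDUCED,
    carrot_chilling_design,
    generate,
)

from conftest import MC_NOISE_SD, MC_REPLICATES, STANDARD_INIT

GEOM = CylinderGeometry(radius=0.022, length=0.040)
TRUTH = ThermalParameters(alpha=CARROT_ALPHA, h_reduced=CARROT_H_REDUCED)

# printed reference covariance of (alpha, h') used by the uncertainty report
REF_COV = np.array([[8.2578e-17, -1.8611e-16],
                    [-1.8611e-16, 5.2435e-16]])


def noiseless_series(n=49, t_max=3600.0, params=TRUTH, n_terms=200):
    times = np.linspace(0.0, t_max, n)
    return ObservationSeries(times=times,
                             temps=center_curve(times, GEOM, params, n_terms),
                             sigmas=np.ones(n))


class TestResiduals:
    def test_zero_at_generating_parameters(self):
        series = noiseless_series()
        delta = residuals(TRUTH, series, GEOM)
        assert series.n == 49
        assert np.max(np.abs(delta)) < 1e-10

    def test_constant_offset_passes_through(self):
        series = noiseless_series()
        shifted = ObservationSeries(times=series.times, temps=series.temps + 0.3,
                                    sigmas=series.sigmas)
        delta = residuals(TRUTH, shifted, GEOM)
        np.testing.assert_allclose(delta, 0.3, atol=1e-10)

    def test_celsius_mode_uses_conditions(self):
        conds = ChillingConditions(t0=19.9, teq=3.5)
        series = noiseless_series()
        celsius = ObservationSeries(
            times=series.times,
            temps=conds.teq + (conds.t0 - conds.teq) * series.temps,
            sigmas=series.sigmas)
        delta = residuals(TRUTH, celsius, GEOM, conditions=conds)
        assert np.max(np.abs(delta)) < 1e-9


class TestSensitivityMatrix:
    def test_alpha_column_nonpositive_after_start(self):
        series = noiseless_series()
        jac = sensitivity_matrix(TRUTH, series, GEOM)
        assert jac.shape == (49, 2)
        late = series.times > 0
        assert np.all(jac[late, 0] <= 0)

    def test_second_order_step_stability(self):
        series = noiseless_series(n=13)
        j1 = sensitivity_matrix(TRUTH, series, GEOM, step=1e-3)
        j2 = sensitivity_matrix(TRUTH, series, GEOM, step=5e-4)
        scale = np.max(np.abs(j1), axis=0)
        np.testing.assert_allclose(j1 / scale, j2 / scale, atol=1e-4)

    def test_initial_instant_insensitive_to_parameters(self):
        series = noiseless_series(n=5)
        jac = sensitivity_matrix(TRUTH, series, GEOM)
        # T(t=0) is the initial condition: only the Bi-dependent truncation
        # deficit (~2e-5) responds to the parameters, far below the
        # later-time sensitivities
        assert abs(jac[0, 0] * TRUTH.alpha) < 1e-4
        assert abs(jac[0, 1] * TRUTH.h_reduced) < 1e-4
        late = np.max(np.abs(jac[1:, 0])) * TRUTH.alpha
        assert late > 100 * abs(jac[0, 0] * TRUTH.alpha)


class TestNormalEquations:
    def test_orthogonal_columns_give_diagonal_m(self):
        jac = np.array([[1.0, 0.0], [0.0, 2.0], [1.0, 0.0]])
        m, c = normal_equations(jac, np.zeros(3), np.ones(3))
        assert m[0, 1] == m[1, 0] == 0.0
        np.testing.assert_array_equal(c, [0.0, 0.0])

    def test_zero_residuals_give_zero_correction(self):
        rng = np.random.default_rng(7)
        jac = rng.normal(size=(10, 2))
        m, c = normal_equations(jac, np.zeros(10), np.ones(10))
        step = np.linalg.solve(m, c)
        np.testing.assert_allclose(step, 0.0, atol=1e-15)

    def test_sigma_scaling_leaves_step_unchanged(self):
        rng = np.random.default_rng(11)
        jac = rng.normal(size=(10, 2))
        delta = rng.normal(size=10)
        m1, c1 = normal_equations(jac, delta, np.ones(10))
        m2, c2 = normal_equations(jac, delta, 2 * np.ones(10))
        np.testing.assert_allclose(m2, m1 / 4, rtol=1e-14)
        np.testing.assert_allclose(c2, c1 / 4, rtol=1e-14)
        np.testing.assert_allclose(np.linalg.solve(m1, c1),
                                   np.linalg.solve(m2, c2), rtol=1e-12)


class TestFit:
    def test_fixed_point_at_truth(self):
        series = noiseless_series()
        result = fit(series, GEOM, init=(TRUTH.alpha, TRUTH.h_reduced))
        assert result.converged
        assert result.iterations <= 2
        assert result.chi2 < 1e-15

    def test_noiseless_recovery_from_standard_start(self):
        series = noiseless_series()
        result = fit(series, GEOM, init=STANDARD_INIT)
        assert result.converged
        assert result.alpha == pytest.approx(TRUTH.alpha, rel=1e-3)
        assert result.h_reduced == pytest.approx(TRUTH.h_reduced, rel=1e-3)

    @pytest.mark.parametrize("alpha", [1e-7, 1.5e-7, 2e-7])
    @pytest.mark.parametrize("bi1", [0.15, 0.3, 1.0, 5.0])
    def test_noiseless_recovery_grid(self, alpha, bi1):
        truth = ThermalParameters(alpha=alpha,
                                  h_reduced=bi1 * alpha / GEOM.radius)
        series = noiseless_series(params=truth, n_terms=100)
        result = fit(series, GEOM, init=STANDARD_INIT, n_terms=100)
        assert result.converged
        assert result.alpha == pytest.approx(alpha, rel=1e-3)
        assert result.h_reduced == pytest.approx(truth.h_reduced, rel=1e-3)

    def test_chi2_nonincreasing_along_accepted_iterations(self):
        design = carrot_chilling_design(noise_sd=0.01, seed=3)
        series = generate(design)
        result = fit(series, GEOM, init=STANDARD_INIT)
        chi2s = [h[2] for h in result.history]
        assert np.all(np.diff(chi2s) <= 1e-12)

    def test_history_and_metadata_recorded(self):
        series = noiseless_series()
        result = fit(series, GEOM, init=STANDARD_INIT)
        assert len(result.history) == result.iterations + 1
        assert result.covariance.shape == (2, 2)
        assert abs(result.correlation) <= 1.0
        d = result.to_dict()
        assert d["converged"] is True

    def test_estimator_sklearn_surface(self):
        design = carrot_chilling_design(noise_sd=0.005, seed=5)
        series = generate(design)
        est = CenterCoolingRegressor(alpha0=STANDARD_INIT[0],
                                     h_reduced0=STANDARD_INIT[1],
                                     rho_cp=1003.0 * 3918.0)
        cloned_params = est.get_params()
        assert cloned_params["alpha0"] == STANDARD_INIT[0]
        est.fit(series.times, series.temps, sigma=series.sigmas)
        assert est.converged_
        assert est.h_H_ == pytest.approx(est.h_reduced_ * 1003.0 * 3918.0)
        pred = est.predict(series.times)
        assert pred.shape == series.temps.shape
        # R^2 through the sklearn scoring interface agrees with the attribute
        assert est.score(series.times, series.temps) == pytest.approx(est.r2_,
                                                                      abs=1e-6)

    def test_requires_minimum_points_and_positive_init(self):
        short = ObservationSeries(times=np.array([0.0, 60.0]),
                                  temps=np.array([1.0, 0.9]),
                                  sigmas=np.ones(2))
        with pytest.raises(ValueError):
            fit(short, GEOM, init=STANDARD_INIT)
        series = noiseless_series(n=5)
        with pytest.raises(ValueError):
            fit(series, GEOM, init=(-1e-7, 1e-6))


class TestMonteCarlo:
    def test_coverage_of_expanded_intervals(self, mc_fits, mc_truth):
        """About 95% of coverage-factor-2 intervals should contain the truth."""
        hits_alpha = hits_h = 0
        for res in mc_fits:
            u_a, u_h = res.expanded_uncertainty
            hits_alpha += abs(res.alpha - mc_truth[0]) <= u_a
            hits_h += abs(res.h_reduced - mc_truth[1]) <= u_h
        for hits in (hits_alpha, hits_h):
            assert 0.90 <= hits / MC_REPLICATES <= 0.99

    def test_mean_recovery_within_combined_standard_error(self, mc_fits, mc_truth):
        alphas = np.array([r.alpha for r in mc_fits])
        se = alphas.std(ddof=1) / np.sqrt(len(alphas))
        assert abs(alphas.mean() - mc_truth[0]) < 2 * se + 1e-12

    def test_parameter_correlation_is_negative(self, mc_fits):
        corrs = np.array([r.correlation for r in mc_fits])
        assert np.all(corrs < 0)

    def test_reported_scatter_matches_empirical_scatter(self, mc_fits):
        # the covariance-derived standard uncertainty should be of the same
        # order as the replicate-to-replicate scatter
        alphas = np.array([r.alpha for r in mc_fits])
        u_mean = np.mean([r.expanded_uncertainty[0] for r in mc_fits]) / 2.0
        assert u_mean == pytest.approx(alphas.std(ddof=1), rel=0.35)


class TestCovarianceReport:
    def test_reference_matrix_summary(self):
        rep = report_from_covariance(REF_COV, rho_cp=1003.0 * 3918.0)
        assert round(rep.correlation, 4) == pytest.approx(-0.8944)
        assert rep.expanded_uncertainty[0] == pytest.approx(0.18e-7, abs=0.005e-7)
        # the h_H-scale expanded uncertainty follows by the rho*Cp factor
        assert rep.h_H_uncertainty == pytest.approx(
            2 * np.sqrt(REF_COV[1, 1]) * 1003.0 * 3918.0)

    def test_identity_covariance(self):
        rep = report_from_covariance(np.eye(2))
        assert rep.correlation == 0.0
        assert rep.expanded_uncertainty == (2.0, 2.0)

    def test_report_from_normal_matrix_roundtrip(self):
        m = np.linalg.inv(REF_COV)
        rep = covariance_report(m)
        np.testing.assert_allclose(rep.covariance, REF_COV, rtol=1e-10)

    def test_singular_matrix_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            covariance_report(np.zeros((2, 2)))


class TestFitStatistics:
    def test_perfect_fit(self):
        y = np.array([1.0, 0.5, 0.25])
        chi2, rmse, r2, sigma_fit = fit_statistics(y, y)
        assert (chi2, rmse, sigma_fit) == (0.0, 0.0, 0.0)
        assert r2 == 1.0

    def test_three_point_hand_arithmetic(self):
        chi2, rmse, r2, sigma_fit = fit_statistics(
            [1.0, 0.5, 0.25], [1.0, 0.4, 0.35])
        assert chi2 == pytest.approx(0.02)
        assert rmse == pytest.approx(np.sqrt(0.02 / 3))
        assert sigma_fit == pytest.approx(np.sqrt(0.02 / 1))

    def test_residual_homogeneity(self):
        y = np.array([1.0, 0.5, 0.25, 0.1])
        model = y + 0.01
        scaled = y + 0.03
        chi2_a, rmse_a, _, _ = fit_statistics(y, model)
        chi2_b, rmse_b, _, _ = fit_statistics(y, scaled)
        assert chi2_b == pytest.approx(9 * chi2_a)
        assert rmse_b == pytest.approx(3 * rmse_a)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_statistics([1.0, 0.5], [1.0, 0.5])


class TestDimensionlessTransform:
    def test_reference_temperatures(self):
        conds = ChillingConditions(t0=19.9, teq=3.5)
        series = ObservationSeries(times=np.array([0.0, 60.0, 120.0]),
                                   temps=np.array([19.9, 3.5, 11.7]),
                                   sigmas=np.ones(3))
        out = to_dimensionless(series, conds)
        np.testing.assert_allclose(out.temps, [1.0, 0.0, 0.5], atol=1e-12)
        # unknown sigmas stay at 1
        np.testing.assert_array_equal(out.sigmas, 1.0)

    def test_known_sigmas_rescaled_and_order_preserved(self):
        conds = ChillingConditions(t0=19.9, teq=3.5)
        series = ObservationSeries(times=np.array([0.0, 60.0]),
                                   temps=np.array([18.0, 15.0]),
                                   sigmas=np.array([0.1, 0.1]))
        out = to_dimensionless(series, conds)
        np.testing.assert_allclose(out.sigmas, 0.1 / 16.4, rtol=1e-12)
        assert out.temps[0] > out.temps[1]
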