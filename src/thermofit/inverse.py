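"""Damped least-squares estimation of (alpha, h') from a center-point cooling curve.

The inverse problem: given measured temperatures ``T_i`` at the geometric
center of a chilled finite cylinder at times ``t_i``, find the thermal
diffusivity ``alpha`` and the reduced heat transfer coefficient
``h' = h_H/(rho*Cp)`` whose analytical forward solution best fits the data
in the weighted least-squares (chi-square) sense

    chi2(a) = sum_i (T_i^exp - T_i^sim(a))^2 / sigma_i^2 ,   a = (alpha, h').

Minimisation follows the Levenberg-Marquardt scheme built on the normal
equations ``M dA = C`` with ``M_jk = sum_i J_ij J_ik / sigma_i^2`` and
``C_j = sum_i delta_i J_ij / sigma_i^2``, damped as
``(M + lambda diag(M)) dA = C``; an accepted step (chi2 does not increase)
divides lambda by 10, a rejected one multiplies it by 10.  Iteration stops
when both relative corrections ``|dA_j / a_j|`` fall below 1e-5.
Sensitivities ``J_ij = dT_i^sim/da_j`` use central finite differences with a
relative step.  At convergence the *undamped* ``M`` is inverted to give the
parameter covariance; expanded uncertainties apply a coverage factor of 2
(about 95.4 % under Gaussian errors).  The covariance is reported unscaled
by default; reduced-chi-square rescaling is available as an option.

The fit operates on dimensionless temperatures
``T* = (T - Teq)/(T0 - Teq)`` by default, with ``sigma_i = 1`` when the
measurement uncertainty is unknown.

The scikit-learn flavoured :class:`CenterCoolingRegressor` is the primary
entry point; the module-level functions (:func:`fit`, :func:`residuals`,
:func:`sensitivity_matrix`, ...) expose the individual steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .eigenmodes import DEFAULT_N_TERMS
from .forward import (
    ChillingConditions,
    CylinderGeometry,
    ThermalParameters,
    center_curve,
)

#: Convergence threshold on both relative parameter corrections.
DEFAULT_TOL = 1e-5
#: Relative step of the central-difference sensitivities.
DEFAULT_FD_STEP = 1e-3
#: Initial Levenberg damping.
DEFAULT_LAMBDA0 = 1e-3
#: Coverage factor of the expanded uncertainties (~95.4 % Gaussian).
COVERAGE_FACTOR = 2.0


@dataclass(frozen=True)
class ObservationSeries:
    """Center-point measurements (t_i, T_i, sigma_i).

    ``sigmas`` of exactly 1.0 conventionally mark unknown measurement
    uncertainty.  ``temps`` may hold degC values or dimensionless T*.
    """

    times: np.ndarray = _dc_field(repr=False)
    temps: np.ndarray = _dc_field(repr=False)
    sigmas: np.ndarray = _dc_field(repr=False)

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        temps = np.asarray(self.temps, dtype=float)
        sigmas = np.asarray(self.sigmas, dtype=float)
        if not (times.shape == temps.shape == sigmas.shape) or times.ndim != 1:
            raise ValueError("times, temps and sigmas must be equal-length 1-D arrays")
        if np.any(np.diff(times) < 0):
            raise ValueError("times must be nondecreasing")
        if np.any(sigmas <= 0):
            raise ValueError("sigmas must be positive")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "temps", temps)
        object.__setattr__(self, "sigmas", sigmas)

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def sigma_known(self) -> bool:
        return not np.all(self.sigmas == 1.0)


def to_dimensionless(series: ObservationSeries,
                     conditions: ChillingConditions) -> ObservationSeries:
    """Transform degC measurements to T* = (T - Teq)/(T0 - Teq).

    Known sigmas are scaled by ``1/|T0 - Teq|``; the all-ones "unknown"
    convention is preserved.
    """
    span = conditions.t0 - conditions.teq
    tstar = (series.temps - conditions.teq) / span
    if series.sigma_known:
        sigmas = series.sigmas / abs(span)
    else:
        sigmas = series.sigmas
    return ObservationSeries(times=series.times, temps=tstar, sigmas=sigmas)


@dataclass(frozen=True)
class CovarianceReport:
    """Covariance-derived uncertainty summary for the two parameters."""

    covariance: np.ndarray = _dc_field(repr=False)
    expanded_uncertainty: tuple  # (u_alpha, u_h_reduced), coverage factor applied
    correlation: float
    h_H_uncertainty: Optional[float] = None  # expanded, on the h_H scale


@dataclass
class FitResult:
    """Converged inverse-problem solution with uncertainty and fit statistics."""

    alpha: float
    h_reduced: float
    covariance: Optional[np.ndarray]
    expanded_uncertainty: Optional[tuple]
    correlation: Optional[float]
    chi2: float
    rmse: float
    r2: float
    sigma_fit: float
    iterations: int
    converged: bool
    history: list  # (alpha, h_reduced, chi2, lambda) per accepted iteration
    h_H: Optional[float] = None
    h_H_uncertainty: Optional[float] = None

    @property
    def params(self) -> ThermalParameters:
        return ThermalParameters(alpha=self.alpha, h_reduced=self.h_reduced)

    def to_dict(self) -> dict:
        """JSON-serialisable summary."""
        return {
            "alpha": self.alpha,
            "h_reduced": self.h_reduced,
            "h_H": self.h_H,
            "covariance": None if self.covariance is None else
                          np.asarray(self.covariance).tolist(),
            "expanded_uncertainty": None if self.expanded_uncertainty is None
                                    else list(self.expanded_uncertainty),
            "h_H_uncertainty": self.h_H_uncertainty,
            "correlation": self.correlation,
            "chi2": self.chi2,
            "rmse": self.rmse,
            "r2": self.r2,
            "sigma_fit": self.sigma_fit,
            "iterations": self.iterations,
            "converged": self.converged,
            "history": [list(h) for h in self.history],
        }


def residuals(params: ThermalParameters, data: ObservationSeries,
              geometry: CylinderGeometry,
              conditions: Optional[ChillingConditions] = None,
              n_terms: int = DEFAULT_N_TERMS) -> np.ndarray:
    """Unweighted residuals ``delta_i = T_i^exp - T_i^sim`` at the center point.

    With *conditions* given the model curve is mapped to degC before
    differencing; otherwise the data are taken as dimensionless.
    """
    sim = center_curve(data.times, geometry, params, n_terms)
    if conditions is not None:
        sim = conditions.teq + (conditions.t0 - conditions.teq) * sim
    return data.temps - sim


def sensitivity_matrix(params: ThermalParameters, data: ObservationSeries,
                       geometry: CylinderGeometry,
                       conditions: Optional[ChillingConditions] = None,
                       step: float = DEFAULT_FD_STEP,
                       n_terms: int = DEFAULT_N_TERMS) -> np.ndarray:
    """N x 2 Jacobian dT_i^sim/da_j by central differences, a = (alpha, h')."""
    if step <= 0:
        raise ValueError("step must be positive")

    def model(a):
        sim = center_curve(data.times, geometry,
                           ThermalParameters(alpha=a[0], h_reduced=a[1]), n_terms)
        if conditions is not None:
            sim = conditions.teq + (conditions.t0 - conditions.teq) * sim
        return sim

    return _fd_jacobian(model, np.array([params.alpha, params.h_reduced]), step)


def _fd_jacobian(model, a: np.ndarray, rel_step: float) -> np.ndarray:
    cols = []
    for j in range(len(a)):
        h = rel_step * abs(a[j])
        if h == 0.0:  # absolute floor for a degenerate (zero) parameter
            h = rel_step
        up, dn = a.copy(), a.copy()
        up[j] += h
        dn[j] -= h
        cols.append((model(up) - model(dn)) / (2.0 * h))
    return np.column_stack(cols)


def normal_equations(jacobian: np.ndarray, resid: np.ndarray,
                     sigmas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted normal-equation pieces (M, C) of ``M dA = C``.

    ``M_jk = sum_i J_ij J_ik / sigma_i^2``; ``C_j = sum_i delta_i J_ij / sigma_i^2``.
    """
    w = 1.0 / np.asarray(sigmas, dtype=float) ** 2
    jw = jacobian * w[:, None]
    return jacobian.T @ jw, jw.T @ np.asarray(resid, dtype=float)


def fit_statistics(observed, model_curve, sigmas=None,
                   n_params: int = 2) -> tuple[float, float, float, float]:
    """(chi2, rmse, r2, sigma_fit) of a model curve against observations.

    chi2 = sum(delta^2/sigma^2); rmse = sqrt(mean delta^2);
    r2 = 1 - SS_res/SS_tot; sigma_fit = sqrt(sum delta^2/(N - n_params)).
    """
    observed = np.asarray(observed, dtype=float)
    model_curve = np.asarray(model_curve, dtype=float)
    n = len(observed)
    if n <= n_params:
        raise ValueError(f"sigma_fit undefined for N <= {n_params} points")
    sigmas = np.ones(n) if sigmas is None else np.asarray(sigmas, dtype=float)
    delta = observed - model_curve
    chi2 = float(np.sum((delta / sigmas) ** 2))
    rmse = float(np.sqrt(np.sum(delta**2) / n))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    r2 = 1.0 - float(np.sum(delta**2)) / ss_tot if ss_tot > 0 else np.nan
    sigma_fit = float(np.sqrt(np.sum(delta**2) / (n - n_params)))
    return chi2, rmse, r2, sigma_fit


def report_from_covariance(cov: np.ndarray, rho_cp: Optional[float] = None,
                           coverage: float = COVERAGE_FACTOR) -> CovarianceReport:
    """Uncertainty summary from a 2x2 parameter covariance matrix."""
    cov = np.asarray(cov, dtype=float)
    u = coverage * np.sqrt(np.diag(cov))
    corr = float(cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1]))
    u_hh = float(u[1] * rho_cp) if rho_cp is not None else None
    return CovarianceReport(covariance=cov,
                            expanded_uncertainty=(float(u[0]), float(u[1])),
                            correlation=corr, h_H_uncertainty=u_hh)


def covariance_report(m_final: np.ndarray, rho_cp: Optional[float] = None,
                      coverage: float = COVERAGE_FACTOR) -> CovarianceReport:
    """Invert the final (undamped) normal matrix and summarise uncertainties."""
    m_final = np.asarray(m_final, dtype=float)
    try:
        cov = np.linalg.inv(m_final)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "final normal matrix is singular; covariance unavailable") from exc
    return report_from_covariance(cov, rho_cp=rho_cp, coverage=coverage)


class CenterCoolingRegressor(RegressorMixin, BaseEstimator):
    """Estimate (alpha, h') of a chilled finite cylinder from its center cooling curve.

    A scikit-learn style regressor: ``X`` is the measurement time in seconds
    (shape ``(n,)`` or ``(n, 1)``), ``y`` the center temperature.  By default
    ``y`` is dimensionless T*; with ``scale="celsius"`` (requires ``t0`` and
    ``teq``) raw degC values are transformed internally before fitting.

    Parameters
    ----------
    radius, length : float
        Cylinder geometry in m.
    t0, teq : float, optional
        Initial and coolant temperature in degC (needed for scale="celsius").
    alpha0 : float
        Starting thermal diffusivity, m^2/s.
    h_reduced0 : float
        Starting reduced heat transfer coefficient h' = h_H/(rho*Cp), m/s.
    rho_cp : float, optional
        Volumetric heat capacity rho*Cp (J/m^3/K); when given the fitted h'
        is also reported on the h_H scale as ``h_H_ = h' * rho_cp``.
    n_terms : int
        Series terms per sub-problem in the forward model.
    fd_step : float
        Relative step of the central-difference sensitivities.
    lambda0 : float
        Initial Levenberg damping.
    tol : float
        Convergence threshold on both relative parameter corrections.
    max_iter : int
        Iteration cap.
    scale : {"dimensionless", "celsius"}
        Scale of the supplied ``y``.
    rescale_covariance : bool
        If True, multiply the covariance by the reduced chi-square
        ``chi2/(N-2)`` before reporting (off by default).

    Attributes
    ----------
    alpha_, h_reduced_ : float
        Fitted parameters.
    h_H_ : float or None
        ``h_reduced_ * rho_cp`` when ``rho_cp`` was given.
    covariance_ : ndarray or None
        2x2 covariance of (alpha, h') from the inverted normal matrix.
    expanded_uncertainty_ : (float, float) or None
        Coverage-factor-2 uncertainties of (alpha, h').
    correlation_ : float or None
        Parameter correlation coefficient.
    chi2_, rmse_, r2_, sigma_fit_ : float
        Goodness-of-fit statistics on the fitted scale.
    n_iter_ : int
    converged_ : bool
    history_ : list of (alpha, h_reduced, chi2, lambda)
    """

    def __init__(self, radius: float = 0.022, length: float = 0.040,
                 t0: Optional[float] = None, teq: Optional[float] = None,
                 alpha0: float = 1e-7, h_reduced0: float = 1e-6,
                 rho_cp: Optional[float] = None,
                 n_terms: int = DEFAULT_N_TERMS,
                 fd_step: float = DEFAULT_FD_STEP,
                 lambda0: float = DEFAULT_LAMBDA0,
                 tol: float = DEFAULT_TOL, max_iter: int = 100,
                 scale: str = "dimensionless",
                 rescale_covariance: bool = False):
        self.radius = radius
        self.length = length
        self.t0 = t0
        self.teq = teq
        self.alpha0 = alpha0
        self.h_reduced0 = h_reduced0
        self.rho_cp = rho_cp
        self.n_terms = n_terms
        self.fd_step = fd_step
        self.lambda0 = lambda0
        self.tol = tol
        self.max_iter = max_iter
        self.scale = scale
        self.rescale_covariance = rescale_covariance

    # -- helpers ----------------------------------------------------------

    def _geometry(self) -> CylinderGeometry:
        return CylinderGeometry(radius=self.radius, length=self.length)

    def _validate_X(self, X) -> np.ndarray:
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        if t.ndim != 1:
            raise ValueError("X must be a 1-D array of times or a single column")
        if np.any(t < 0):
            raise ValueError("times must be nonnegative")
        return t

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y, sigma=None):
        """Run the damped least-squares iteration.

        Parameters
        ----------
        X : array-like, shape (n,) or (n, 1)
            Measurement times in seconds.
        y : array-like, shape (n,)
            Center temperatures (scale per the ``scale`` parameter).
        sigma : array-like, optional
            Measurement uncertainties on the same scale as ``y``;
            all-ones (the default) means unknown.
        """
        t = self._validate_X(X)
        y = np.asarray(y, dtype=float)
        if y.shape != t.shape:
            raise ValueError("X and y must have matching lengths")
        if len(t) < 3:
            raise ValueError("at least 3 observations are required")
        sigma = np.ones_like(y) if sigma is None else np.asarray(sigma, dtype=float)
        series = ObservationSeries(times=t, temps=y, sigmas=sigma)

        if self.scale == "celsius":
            if self.t0 is None or self.teq is None:
                raise ValueError("scale='celsius' requires t0 and teq")
            series = to_dimensionless(
                series, ChillingConditions(t0=self.t0, teq=self.teq))
        elif self.scale != "dimensionless":
            raise ValueError("scale must be 'dimensionless' or 'celsius'")

        geometry = self._geometry()
        if self.alpha0 <= 0 or self.h_reduced0 <= 0:
            raise ValueError("initial parameter values must be positive")

        def model(a):
            return center_curve(series.times, geometry,
                                ThermalParameters(alpha=a[0], h_reduced=a[1]),
                                self.n_terms)

        out = _levenberg_marquardt(
            model, np.array([self.alpha0, self.h_reduced0], dtype=float),
            series.temps, series.sigmas, fd_step=self.fd_step,
            lambda0=self.lambda0, tol=self.tol, max_iter=self.max_iter)
        a, m_final, self.n_iter_, self.converged_, self.history_ = out

        self.alpha_ = float(a[0])
        self.h_reduced_ = float(a[1])
        self.h_H_ = self.h_reduced_ * self.rho_cp if self.rho_cp is not None else None

        curve = model(a)
        self.chi2_, self.rmse_, self.r2_, self.sigma_fit_ = fit_statistics(
            series.temps, curve, series.sigmas)

        self.covariance_ = None
        self.expanded_uncertainty_ = None
        self.correlation_ = None
        self.h_H_uncertainty_ = None
        try:
            cov = np.linalg.inv(m_final)
            if self.rescale_covariance:
                cov = cov * self.chi2_ / (series.n - 2)
            rep = report_from_covariance(cov, rho_cp=self.rho_cp)
            self.covariance_ = rep.covariance
            self.expanded_uncertainty_ = rep.expanded_uncertainty
            self.correlation_ = rep.correlation
            self.h_H_uncertainty_ = rep.h_H_uncertainty
        except np.linalg.LinAlgError:
            pass  # singular normal matrix: parameters stand, uncertainty flagged None
        return self

    def predict(self, X):
        """Center temperature at the fitted parameters, on the fitted y-scale."""
        t = self._validate_X(X)
        order = np.argsort(t, kind="stable")
        curve = np.empty_like(t)
        curve[order] = center_curve(
            t[order], self._geometry(),
            ThermalParameters(alpha=self.alpha_, h_reduced=self.h_reduced_),
            self.n_terms)
        if self.scale == "celsius":
            curve = self.teq + (self.t0 - self.teq) * curve
        return curve

    def result_(self) -> FitResult:
        """Bundle the fitted attributes into a :class:`FitResult`."""
        return FitResult(
            alpha=self.alpha_, h_reduced=self.h_reduced_,
            covariance=self.covariance_,
            expanded_uncertainty=self.expanded_uncertainty_,
            correlation=self.correlation_, chi2=self.chi2_, rmse=self.rmse_,
            r2=self.r2_, sigma_fit=self.sigma_fit_, iterations=self.n_iter_,
            converged=self.converged_, history=self.history_,
            h_H=self.h_H_, h_H_uncertainty=self.h_H_uncertainty_)


def _levenberg_marquardt(model, a0, y, sigmas, fd_step, lambda0, tol, max_iter):
    """Damped normal-equation iteration; returns (a, M_undamped, n_iter, converged, history)."""
    a = np.asarray(a0, dtype=float).copy()
    curve = model(a)
    delta = y - curve
    chi2 = float(np.sum((delta / sigmas) ** 2))
    lam = lambda0
    history = [(a[0], a[1], chi2, lam)]
    converged = False
    n_iter = 0

    for n_iter in range(1, max_iter + 1):
        jac = _fd_jacobian(model, a, fd_step)
        m, c = normal_equations(jac, delta, sigmas)
        accepted = False
        rel = None
        for _ in range(60):
            try:
                step = np.linalg.solve(m + lam * np.diag(np.diag(m)), c)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            # keep parameters positive: halve a step that would cross zero
            for _ in range(60):
                if np.all(a + step > 0):
                    break
                step = step / 2.0
            new_a = a + step
            new_curve = model(new_a)
            new_delta = y - new_curve
            new_chi2 = float(np.sum((new_delta / sigmas) ** 2))
            if new_chi2 <= chi2:
                rel = np.abs(step) / np.abs(a)
                a, curve, delta, chi2 = new_a, new_curve, new_delta, new_chi2
                lam = max(lam / 10.0, 1e-14)
                accepted = True
                break
            lam *= 10.0
            if lam > 1e14:
                break
        history.append((a[0], a[1], chi2, lam))
        if not accepted:
            break
        if np.all(rel < tol):
            converged = True
            break

    jac = _fd_jacobian(model, a, fd_step)
    m_final, _ = normal_equations(jac, delta, sigmas)
    return a, m_final, n_iter, converged, history


def fit(data: ObservationSeries, geometry: CylinderGeometry,
        conditions: Optional[ChillingConditions] = None,
        init: tuple = (1e-7, 1e-6), *, rho_cp: Optional[float] = None,
        data_scale: str = "dimensionless", n_terms: int = DEFAULT_N_TERMS,
        fd_step: float = DEFAULT_FD_STEP, lambda0: float = DEFAULT_LAMBDA0,
        tol: float = DEFAULT_TOL, max_iter: int = 100,
        rescale_covariance: bool = False) -> FitResult:
    """Functional wrapper over :class:`CenterCoolingRegressor`.

    *init* is ``(alpha0, h_reduced0)``.  With ``data_scale="celsius"`` the
    observations are transformed to T* using *conditions* before fitting.
    """
    est = CenterCoolingRegressor(
        radius=geometry.radius, length=geometry.length,
        t0=None if conditions is None else conditions.t0,
        teq=None if conditions is None else conditions.teq,
        alpha0=init[0], h_reduced0=init[1], rho_cp=rho_cp, n_terms=n_terms,
        fd_step=fd_step, lambda0=lambda0, tol=tol, max_iter=max_iter,
        scale=data_scale, rescale_covariance=rescale_covariance)
    est.fit(data.times, data.temps, sigma=data.sigmas)
    return est.result_()
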