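"""Analytical transient temperature field of a convectively chilled finite cylinder.

The dimensionless temperature ``T* = (T - Teq)/(T0 - Teq)`` of a homogeneous
finite cylinder, initially uniform at ``T0`` and cooled by a constant-``h``
convective boundary into a medium at ``Teq``, is the double eigenfunction
series

    T*(r, y, t) = sum_n sum_m A_n A_m J0(mu_n r/R) cos(mu_m y/(L/2))
                  * exp(-(mu_n^2/R^2 + mu_m^2/(L/2)^2) * alpha * t)

with the radial eigenpairs (mu_n, A_n) of an infinite cylinder at
``Bi1 = h' R / alpha`` and the axial eigenpairs (mu_m, A_m) of an infinite
wall at ``Bi2 = h' (L/2) / alpha``, where ``h' = h_H/(rho*Cp)`` is the
reduced heat transfer coefficient.  With a rectangular truncation (N terms
in each factor) the double sum factors exactly into the product of the two
one-dimensional partial sums, which is how it is evaluated here.

Coordinates: ``r`` in ``[0, R]`` from the axis, ``y`` in ``[-L/2, L/2]``
from the mid-plane.  Temperatures are handled in degrees Celsius; only
differences and ratios enter the model.  At ``t = 0`` the truncated series
is returned as-is (close to, but not clamped to, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field
from functools import lru_cache

import numpy as np
from scipy import special

from .eigenmodes import (
    CYLINDER,
    DEFAULT_N_TERMS,
    DEFAULT_TOL,
    WALL,
    EigenExpansion,
    is_infinite_biot,
)

LUMPED = "lumped"
THIRD_KIND = "third_kind"
FIRST_KIND = "first_kind"

#: Below this Biot number internal gradients are negligible (lumped model).
LUMPED_BIOT = 0.1
#: Above this Biot number the boundary is practically of the first kind.
FIRST_KIND_BIOT = 40.0


@dataclass(frozen=True)
class CylinderGeometry:
    """Finite solid cylinder, origin at the geometric center.

    Attributes
    ----------
    radius : float
        Cylinder radius R in m.
    length : float
        Full cylinder length L in m (the axial domain is [-L/2, L/2]).
    """

    radius: float
    length: float

    def __post_init__(self):
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("radius and length must be positive")

    @property
    def half_length(self) -> float:
        return self.length / 2.0

    @property
    def volume(self) -> float:
        return np.pi * self.radius**2 * self.length


@dataclass(frozen=True)
class ChillingConditions:
    """Initial product temperature and coolant (equilibrium) temperature, degC."""

    t0: float
    teq: float

    def __post_init__(self):
        if self.t0 == self.teq:
            raise ValueError("t0 must differ from teq (dimensionless transform undefined)")


@dataclass(frozen=True)
class ThermalParameters:
    """The two unknowns of the inverse problem.

    Attributes
    ----------
    alpha : float
        Thermal diffusivity, m^2/s.
    h_reduced : float
        Reduced heat transfer coefficient h' = h_H/(rho*Cp), m/s.
    """

    alpha: float
    h_reduced: float

    def __post_init__(self):
        if self.alpha <= 0 or self.h_reduced <= 0:
            raise ValueError("alpha and h_reduced must be positive")

    def biot(self, geometry: CylinderGeometry) -> tuple[float, float]:
        """(Bi1, Bi2) = (h' R / alpha, h' (L/2) / alpha)."""
        return (self.h_reduced * geometry.radius / self.alpha,
                self.h_reduced * geometry.half_length / self.alpha)


@dataclass(frozen=True)
class TemperatureField:
    """Dimensionless temperature matrix on an (r, y) grid at one instant."""

    r_grid: np.ndarray = _dc_field(repr=False)
    y_grid: np.ndarray = _dc_field(repr=False)
    time: float = 0.0
    values: np.ndarray = _dc_field(default=None, repr=False)  # shape (len(r), len(y))

    def to_frame(self):
        """Long-format DataFrame with columns r, y, t, T_star (for CSV export)."""
        import pandas as pd

        rr, yy = np.meshgrid(self.r_grid, self.y_grid, indexing="ij")
        return pd.DataFrame({
            "r": rr.ravel(),
            "y": yy.ravel(),
            "t": self.time,
            "T_star": self.values.ravel(),
        })


@lru_cache(maxsize=512)
def _cached_expansion(kind: str, biot: float, n_terms: int, tol: float) -> EigenExpansion:
    return EigenExpansion.third_kind(kind, biot, n_terms, tol)


def _expansions(geometry, params, n_terms, biot=None, tol=DEFAULT_TOL):
    bi1, bi2 = params.biot(geometry) if biot is None else biot
    bi1 = np.inf if is_infinite_biot(bi1) else float(bi1)
    bi2 = np.inf if is_infinite_biot(bi2) else float(bi2)
    return (_cached_expansion(CYLINDER, bi1, int(n_terms), float(tol)),
            _cached_expansion(WALL, bi2, int(n_terms), float(tol)))


def _radial_sum(r, times, expansion, alpha, radius):
    """Partial sum over the radial eigenmodes; shape (len(times), len(r))."""
    mu = expansion.roots
    decay = np.exp(-np.outer(np.asarray(times, float), alpha * (mu / radius) ** 2))
    shape = special.j0(np.outer(np.asarray(r, float) / radius, mu))  # (Nr, N)
    return decay @ (expansion.coeffs * shape).T


def _axial_sum(y, times, expansion, alpha, half_length):
    """Partial sum over the axial eigenmodes; shape (len(times), len(y))."""
    mu = expansion.roots
    decay = np.exp(-np.outer(np.asarray(times, float), alpha * (mu / half_length) ** 2))
    shape = np.cos(np.outer(np.asarray(y, float) / half_length, mu))  # (Ny, N)
    return decay @ (expansion.coeffs * shape).T


def _check_point(r, y, geometry):
    r = np.asarray(r, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(r < 0) or np.any(r > geometry.radius):
        raise ValueError(f"radial position outside [0, {geometry.radius}]")
    if np.any(np.abs(y) > geometry.half_length):
        raise ValueError(f"axial position outside [-{geometry.half_length}, {geometry.half_length}]")
    return r, y


def _check_times(t):
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    return t


def dimensionless_temperature(point, t, geometry: CylinderGeometry,
                              params: ThermalParameters,
                              n_terms: int = DEFAULT_N_TERMS, *,
                              biot=None) -> float:
    """Dimensionless temperature T*(r, y, t) at a single point and time.

    Parameters
    ----------
    point : (float, float)
        ``(r, y)`` in meters; ``0 <= r <= R``, ``-L/2 <= y <= L/2``.
    t : float
        Time in seconds, ``>= 0``.
    biot : (float, float), optional
        Explicit ``(Bi1, Bi2)`` overriding the pair derived from *params*
        (useful for regime studies where the Biot numbers are prescribed
        independently of alpha).
    """
    r, y = _check_point(*point, geometry)
    times = _check_times(t)
    exp_r, exp_y = _expansions(geometry, params, n_terms, biot)
    sr = _radial_sum(np.atleast_1d(r), times, exp_r, params.alpha, geometry.radius)
    sy = _axial_sum(np.atleast_1d(y), times, exp_y, params.alpha, geometry.half_length)
    return float(sr[0, 0] * sy[0, 0])


def temperature(point, t, geometry, params, conditions: ChillingConditions,
                n_terms: int = DEFAULT_N_TERMS, *, biot=None) -> float:
    """Dimensional temperature ``T = Teq + (T0 - Teq) * T*`` in degC."""
    tstar = dimensionless_temperature(point, t, geometry, params, n_terms, biot=biot)
    return conditions.teq + (conditions.t0 - conditions.teq) * tstar


def center_curve(times, geometry, params, n_terms: int = DEFAULT_N_TERMS, *,
                 biot=None) -> np.ndarray:
    """T*(0, 0, t) for an array of times (nonnegative, nondecreasing).

    At the center J0(0) = cos(0) = 1, so the series reduces to the product of
    the plain coefficient-weighted exponential sums.
    """
    times = _check_times(times)
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be nondecreasing")
    exp_r, exp_y = _expansions(geometry, params, n_terms, biot)
    sr = _radial_sum([0.0], times, exp_r, params.alpha, geometry.radius)
    sy = _axial_sum([0.0], times, exp_y, params.alpha, geometry.half_length)
    return sr[:, 0] * sy[:, 0]


def curve_at(point, times, geometry, params, n_terms: int = DEFAULT_N_TERMS, *,
             biot=None) -> np.ndarray:
    """T*(r, y, t) along an array of times at one fixed point."""
    r, y = _check_point(*point, geometry)
    times = _check_times(times)
    exp_r, exp_y = _expansions(geometry, params, n_terms, biot)
    sr = _radial_sum(np.atleast_1d(r), times, exp_r, params.alpha, geometry.radius)
    sy = _axial_sum(np.atleast_1d(y), times, exp_y, params.alpha, geometry.half_length)
    return sr[:, 0] * sy[:, 0]


def field(r_grid, y_grid, t, geometry, params, n_terms: int = DEFAULT_N_TERMS, *,
          biot=None) -> TemperatureField:
    """Dimensionless temperature on the tensor grid r_grid x y_grid at time t."""
    r, y = _check_point(r_grid, y_grid, geometry)
    r = np.atleast_1d(r)
    y = np.atleast_1d(y)
    times = _check_times(t)
    exp_r, exp_y = _expansions(geometry, params, n_terms, biot)
    sr = _radial_sum(r, times, exp_r, params.alpha, geometry.radius)       # (1, Nr)
    sy = _axial_sum(y, times, exp_y, params.alpha, geometry.half_length)   # (1, Ny)
    values = np.outer(sr[0], sy[0])
    return TemperatureField(r_grid=r, y_grid=y, time=float(times[0]), values=values)


def max_center_surface_gap(geometry, params, t_max: float, dt: float = 1.0,
                           n_terms: int = DEFAULT_N_TERMS, *,
                           biot=None) -> tuple[float, float]:
    """Maximum of T*(0,0,t) - T*(R,0,t) on the grid {0, dt, ..., t_max}.

    Returns ``(gap, t_at_max)``.  The gap measures how far the center lags
    the lateral surface during the transient; it vanishes in the lumped
    regime and grows with the Biot numbers.
    """
    if dt <= 0 or t_max <= 0:
        raise ValueError("dt and t_max must be positive")
    times = np.arange(0.0, t_max + dt / 2.0, dt)
    center = center_curve(times, geometry, params, n_terms, biot=biot)
    surface = curve_at((geometry.radius, 0.0), times, geometry, params,
                       n_terms, biot=biot)
    gap = center - surface
    i = int(np.argmax(gap))
    return float(gap[i]), float(times[i])


def classify_regime(bi1: float, bi2: float) -> str:
    """Heat-transfer regime from the two Biot numbers.

    ``lumped`` if both are below 0.1 (internal gradients negligible),
    ``first_kind`` if both exceed 40 (surface temperature prescribed),
    ``third_kind`` otherwise.
    """
    if bi1 < 0 or bi2 < 0:
        raise ValueError("Biot numbers must be >= 0")
    if bi1 < LUMPED_BIOT and bi2 < LUMPED_BIOT:
        return LUMPED
    if bi1 > FIRST_KIND_BIOT and bi2 > FIRST_KIND_BIOT:
        return FIRST_KIND
    return THIRD_KIND


def volume_average(field_: TemperatureField) -> float:
    """Volume-averaged T* by trapezoidal integration with r-weighting."""
    r = field_.r_grid
    y = field_.y_grid
    inner = np.trapezoid(field_.values * r[:, None], r, axis=0)
    total = np.trapezoid(inner, y)
    norm = np.trapezoid(r, r) * (y[-1] - y[0])
    return float(total / norm)
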