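"""Thermophysical property correlations and derived quantities for moist foods.

Moisture-based affine correlations (wet-basis moisture ``Xwb`` in percent):

* Fikiin specific heat:      ``Cp = 1382 + 2805 * Xwb/100``  (J/kg/K)
* Riedel thermal diffusivity: ``alpha = 0.88e-7 + 0.6e-7 * Xwb/100`` (m^2/s)
* Sweat thermal conductivity: ``k = 0.148 + 0.493 * Xwb/100``  (W/m/K)

plus density from direct mass/volume measurement, the identity
``k = alpha * rho * Cp`` and the two Biot numbers of a finite cylinder.
The correlations are intended for high-moisture plant tissue; a soft
warning is emitted outside 60-98 % moisture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .forward import CylinderGeometry

_SOFT_RANGE = (60.0, 98.0)


def _check_moisture(moisture_wb: float) -> float:
    if not 0.0 <= moisture_wb <= 100.0:
        raise ValueError(f"wet-basis moisture must be in [0, 100] %, got {moisture_wb}")
    if not _SOFT_RANGE[0] <= moisture_wb <= _SOFT_RANGE[1]:
        warnings.warn(
            f"moisture {moisture_wb} % is outside the usual validity range "
            f"{_SOFT_RANGE} of the food correlations", stacklevel=3)
    return float(moisture_wb)


def fikiin_cp(moisture_wb: float) -> float:
    """Specific heat (J/kg/K) from wet-basis moisture (%), Fikiin model."""
    x = _check_moisture(moisture_wb)
    return 1382.0 + 2805.0 * x / 100.0


def riedel_alpha(moisture_wb: float) -> float:
    """Thermal diffusivity (m^2/s) from wet-basis moisture (%), Riedel correlation."""
    x = _check_moisture(moisture_wb)
    return 0.88e-7 + 0.6e-7 * x / 100.0


def sweat_k(moisture_wb: float) -> float:
    """Thermal conductivity (W/m/K) from wet-basis moisture (%), Sweat correlation."""
    x = _check_moisture(moisture_wb)
    return 0.148 + 0.493 * x / 100.0


def density_from_mass(mass: float, geometry: CylinderGeometry) -> float:
    """Density rho = m / (pi R^2 L) in kg/m^3."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    return mass / geometry.volume


def conductivity_from_alpha(alpha: float, rho: float, cp: float) -> float:
    """Thermal conductivity k = alpha * rho * Cp (W/m/K)."""
    return alpha * rho * cp


def biot_numbers(h_H: float, geometry: CylinderGeometry, k: float) -> tuple[float, float]:
    """(Bi1, Bi2) = (h_H R / k, h_H (L/2) / k) for a finite cylinder.

    Bi1 belongs to the radial (infinite cylinder) sub-problem, Bi2 to the
    axial (infinite wall) one.
    """
    if k <= 0:
        raise ValueError("thermal conductivity must be positive")
    if h_H < 0:
        raise ValueError("heat transfer coefficient must be >= 0")
    return h_H * geometry.radius / k, h_H * geometry.half_length / k


@dataclass(frozen=True)
class ProductProperties:
    """Bundle of product properties; any subset may be present.

    Fields are positive when set; when alpha, rho, cp and k are all
    present they satisfy ``k = alpha * rho * cp`` up to rounding.
    """

    moisture_wb: Optional[float] = None
    mass: Optional[float] = None
    rho: Optional[float] = None
    cp: Optional[float] = None
    k: Optional[float] = None
    alpha: Optional[float] = None
    h_H: Optional[float] = None

    def __post_init__(self):
        for name in ("mass", "rho", "cp", "k", "alpha", "h_H"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when set")

    @classmethod
    def from_measurements(cls, moisture_wb: float, mass: float,
                          geometry: CylinderGeometry) -> "ProductProperties":
        """Correlation-based property set from moisture and measured mass."""
        rho = density_from_mass(mass, geometry)
        cp = fikiin_cp(moisture_wb)
        alpha = riedel_alpha(moisture_wb)
        return cls(moisture_wb=moisture_wb, mass=mass, rho=rho, cp=cp,
                   alpha=alpha, k=conductivity_from_alpha(alpha, rho, cp))
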