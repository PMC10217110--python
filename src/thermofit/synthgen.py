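"""Synthetic center-point cooling curves with known ground truth.

Generates observation series from the analytical forward model plus
additive, independent Gaussian noise, for estimator testing and
Monte-Carlo calibration of the reported uncertainties.  Noise is applied
on the dimensionless scale by default (the scale the fit operates on); a
degC-scale option is provided.  The default design emulates chilling a
cylindrical carrot piece under natural convection: R = 0.022 m,
L = 0.040 m, T0 = 19.9 degC, Teq = 3.5 degC, 49 equally spaced samples
over one hour, with truth alpha = 1.43e-7 m^2/s and
h' = 6.92/(1003*3918) m/s (Bi1 ~ 0.271, Bi2 ~ 0.246).
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field, replace

import numpy as np

from .eigenmodes import DEFAULT_N_TERMS
from .forward import ChillingConditions, CylinderGeometry, ThermalParameters, center_curve
from .inverse import ObservationSeries

#: Default truth of the carrot chilling design.
CARROT_ALPHA = 1.43e-7
CARROT_H_REDUCED = 6.92 / (1003.0 * 3918.0)
CARROT_GEOMETRY = CylinderGeometry(radius=0.022, length=0.040)
CARROT_CONDITIONS = ChillingConditions(t0=19.9, teq=3.5)
#: Typical center-point measurement scatter on the dimensionless scale.
DEFAULT_NOISE_SD = 0.005


@dataclass(frozen=True)
class SynthDesign:
    """Ground-truth recipe for one synthetic cooling experiment.

    ``noise_sd`` is the Gaussian noise standard deviation on the scale
    selected by ``scale`` ("dimensionless" or "celsius"); 0 produces a
    noiseless curve with the sigma column set to 1 ("unknown").
    """

    geometry: CylinderGeometry
    conditions: ChillingConditions
    truth: ThermalParameters
    times: np.ndarray = _dc_field(repr=False)
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    scale: str = "dimensionless"
    n_terms: int = DEFAULT_N_TERMS

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(times) < 0):
            raise ValueError("times must be nondecreasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.scale not in ("dimensionless", "celsius"):
            raise ValueError("scale must be 'dimensionless' or 'celsius'")
        object.__setattr__(self, "times", times)

    def with_seed(self, seed: int) -> "SynthDesign":
        return replace(self, seed=seed)


def generate(design: SynthDesign) -> ObservationSeries:
    """Draw one observation series from the design.

    The noiseless curve is the forward center solution at the design truth;
    noise is i.i.d. Gaussian from ``numpy.random.default_rng(design.seed)``.
    The sigma column records ``noise_sd`` (or 1.0 when noiseless, the
    "uncertainty unknown" convention).
    """
    tstar = center_curve(design.times, design.geometry, design.truth,
                         design.n_terms)
    if design.scale == "celsius":
        c = design.conditions
        base = c.teq + (c.t0 - c.teq) * tstar
    else:
        base = tstar
    if design.noise_sd > 0:
        rng = np.random.default_rng(design.seed)
        base = base + rng.normal(0.0, design.noise_sd, size=base.shape)
        sigmas = np.full_like(base, design.noise_sd)
    else:
        sigmas = np.ones_like(base)
    return ObservationSeries(times=design.times, temps=base, sigmas=sigmas)


def carrot_chilling_design(noise_sd: float = DEFAULT_NOISE_SD, seed: int = 0,
                           scale: str = "dimensionless") -> SynthDesign:
    """The default study design: carrot cylinder chilled under natural convection."""
    return SynthDesign(
        geometry=CARROT_GEOMETRY,
        conditions=CARROT_CONDITIONS,
        truth=ThermalParameters(alpha=CARROT_ALPHA, h_reduced=CARROT_H_REDUCED),
        times=np.linspace(0.0, 3600.0, 49),
        noise_sd=noise_sd,
        seed=seed,
        scale=scale,
    )
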