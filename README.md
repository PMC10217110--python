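# thermofit

Estimate the thermal diffusivity and surface heat transfer coefficient of a
chilled cylindrical product — a piece of cut vegetable, typically — from a
single temperature record taken at its geometric center.

Chilling is the step of minimal processing where a product initially at room
temperature is brought to refrigeration temperature. Designing that step
needs two quantities that are awkward to measure directly: the thermal
diffusivity α = k/(ρC_p) of the tissue and the convective heat transfer
coefficient h_H between the product surface and the cold air. `thermofit`
obtains both by the inverse method: it fits the analytical solution of the
transient heat conduction equation for a finite cylinder to the measured
center-point cooling curve.

## Model

For a homogeneous finite cylinder (radius R, length L, origin at the
geometric center), uniform initial temperature T₀, constant coolant
temperature T_eq and a convective (third-kind) boundary with the same h_H on
all faces, the dimensionless temperature T\* = (T − T_eq)/(T₀ − T_eq) is the
double eigenfunction series

```
T*(r, y, t) = Σₙ Σₘ Aₙ Aₘ J₀(μₙ r/R) cos(μₘ y/(L/2))
              · exp(−(μₙ²/R² + μₘ²/(L/2)²) α t)
```

where μₙ solve μ J₁(μ) = Bi₁ J₀(μ) (infinite cylinder, Bi₁ = h_H R/k) and
μₘ solve μ sin μ = Bi₂ cos μ (infinite wall, Bi₂ = h_H (L/2)/k). The first
200 roots of each characteristic equation are found by bisection on
analytically guaranteed brackets to an interval tolerance of 10⁻¹².

The model depends on the data only through α and the reduced coefficient
h′ = h_H/(ρC_p), so those are the two fitted parameters. Fitting is damped
least squares (Levenberg–Marquardt on the weighted normal equations), with
central-difference sensitivities, stopping when both relative corrections
fall below 10⁻⁵. The inverse of the final undamped normal matrix is the
parameter covariance; expanded uncertainties use a coverage factor of 2
(≈95.4 %). Moisture-based correlations (Fikiin C_p, Riedel α, Sweat k) and
ρ = m/V provide the property chain that converts h′ back to h_H and α to k.

## Worked example

Generate a synthetic chilling experiment with known ground truth
(α = 1.43×10⁻⁷ m²/s, h_H = 6.92 W/m²/K, R = 22 mm, L = 40 mm,
T₀ = 19.9 °C, T_eq = 3.5 °C, 0.08 °C Gaussian sensor noise) and refit it:

```sh
$ thermofit synth --noise-sd 0.08 --seed 7 --out exp.txt
$ thermofit fit --data exp.txt --radius 0.022 --length 0.040 \
    --t0 19.9 --teq 3.5 --rho 1003 --cp 3918 --report report.json
converged: True after 5 iterations
alpha     = 1.48208e-07 m^2/s
h'        = 1.75307e-06 m/s
h_H       = 6.88913 W/m^2/K
k         = 0.582421 W/m/K
U(alpha)  = 7.34e-09 m^2/s (coverage factor 2)
U(h')     = 2.86e-08 m/s (coverage factor 2)
corr      = -0.9218
Bi1, Bi2  = 0.260, 0.237 (third_kind)
chi2 = 32.95  RMSE = 0.004  R2 = 0.9994  sigma_fit = 0.004085
```

The fitted α = (1.48 ± 0.07)×10⁻⁷ m²/s and h_H = 6.89 W/m²/K recover the
generating values within their expanded uncertainties; the negative
correlation (−0.92) between α and h′ is characteristic of two-parameter
cooling-curve fits. Both Biot numbers fall between 0.1 and 40, confirming
the convective (third-kind) boundary regime: neither a lumped model nor a
prescribed-surface-temperature model would be adequate.

The same workflow in Python, scikit-learn style:

```python
import numpy as np
from thermofit import CenterCoolingRegressor
from thermofit.synthgen import carrot_chilling_design, generate

series = generate(carrot_chilling_design(noise_sd=0.005, seed=7))
est = CenterCoolingRegressor(alpha0=1e-7, h_reduced0=1e-6,
                             rho_cp=1003 * 3918).fit(
    series.times, series.temps, sigma=series.sigmas)
print(est.alpha_, est.h_H_, est.expanded_uncertainty_)
```

Other subcommands: `thermofit simulate` (cooling curve at any point),
`thermofit field` (full (r, y) temperature field as CSV),
`thermofit props` (moisture-correlation property report).

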