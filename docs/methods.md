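# Methods

## Forward model

The governing equation is transient heat conduction in cylindrical
coordinates with radial and axial symmetry,
∂T/∂t = α [ (1/r) ∂/∂r (r ∂T/∂r) + ∂²T/∂y² ],
under the assumptions: no internal heat generation; uniform known initial
temperature; homogeneous, isotropic finite cylinder; constant
thermophysical properties over the chilling range (ΔT < 20 °C); a
convective boundary with one h_H on all faces; constant coolant
temperature. Separation of variables gives the product of an
infinite-cylinder solution (Bessel eigenfunctions J₀, Biot number
Bi₁ = h_H R/k) and an infinite-wall solution (cosine eigenfunctions,
Bi₂ = h_H (L/2)/k).

Series coefficients, convective boundary:

- cylinder: Aₙ = 2 Bi₁ / (J₀(μₙ)(Bi₁² + μₙ²)), with μ J₁(μ) = Bi₁ J₀(μ);
- wall: Aₘ = (−1)^{m+1} 2 Bi₂ √(Bi₂² + μₘ²) / (μₘ (Bi₂² + Bi₂ + μₘ²)),
  with μ sin μ = Bi₂ cos μ.

In the prescribed-surface limit (Bi → ∞, practically Bi > 40) these become
Aₙ = 2/(μₙ J₁(μₙ)) at the zeros of J₀ and Aₘ = (−1)^{m+1} 2/μₘ at the odd
multiples of π/2. Both limits are verified in the tests, as is the
algebraic equivalence of the cylinder coefficient with the textbook form
2 J₁(μ)/(μ (J₀² + J₁²)) via the eigencondition.

### Eigenvalue solver

Roots are isolated in analytically guaranteed brackets — cylinder root n
between the (n−1)-th zero of J₁ (counting 0) and the n-th zero of J₀; wall
root m in ((m−1)π, (m−1)π + π/2) — and found by bisection, vectorised over
all brackets, stopping when the bracket width is below 10⁻¹² (default; the
`tol` argument exposes it). One sign change per bracket holds for every
Bi > 0, so the solver cannot skip or duplicate roots. Bi = 0 is rejected
(the convective eigenproblem degenerates; physically there is no cooling);
Bi > 10⁸ is treated as infinite. Default truncation is 200 terms per
sub-problem.

### Evaluation

With a rectangular truncation the double series factors exactly into the
product of the two one-dimensional partial sums; the evaluator computes
that product fully vectorised over points and times, which is both faster
and numerically identical to the nested double sum (the tests compare
against a literal nested-loop evaluation with independently found roots).
Expansions are cached per (kind, Bi, n_terms, tol).

Numerical notes:

- t = 0 returns the truncated series value, ≈ 1 − 2×10⁻⁵ at the default
  design's Biot numbers and 200 terms; it is not clamped to 1. The
  truncation deficit grows with Bi (≈ 3×10⁻³ at Bi = 40 with 200 terms).
- Temperatures are handled in °C throughout; only differences and ratios
  enter the model, so no Kelvin conversion is needed.
- Forward operations accept an explicit `biot=(Bi1, Bi2)` override. This
  serves regime studies where the Biot pair is prescribed independently of
  α, including pairs that are not exactly representable by a single
  (α, h′) combination because of rounding.
- The center–surface gap scan uses a uniform time grid (default step 1 s);
  the gap curve is smooth and very flat near its maximum (variation ~2×10⁻⁴
  over ±50 s at the default parameters), so the *magnitude* of the peak is
  robust while its *instant* is sensitive to sub-millikelvin model
  differences. An independent finite-difference solve of the governing
  equation (axisymmetric, Robin boundaries, BDF time stepping) reproduces
  the series solution's peak instant to within the scan step.

## Regime classification

Bi < 0.1 on both sub-problems: lumped (internal gradients negligible, only
h_H identifiable). Bi > 40 on both: first kind (surface temperature
prescribed, only α identifiable). Otherwise: third kind, where both
parameters are identifiable from a single center curve — the regime the
estimator is designed for.

## Property correlations

Wet-basis moisture X_wb in percent, valid range guarded to [0, 100] with a
soft warning outside [60, 98]:

- C_p = 1382 + 2805 X_wb/100 (J/kg/K, Fikiin)
- α = 0.88×10⁻⁷ + 0.6×10⁻⁷ X_wb/100 (m²/s, Riedel)
- k = 0.148 + 0.493 X_wb/100 (W/m/K, Sweat)

plus ρ = m/(πR²L) and k = αρC_p. The three correlations are mutually
compatible to within ~10 % over 80–95 % moisture (k from the α-chain at
ρ = 1000 vs. Sweat's k); this is documented, not asserted tighter, because
they come from independent data sets. Derived Biot numbers are computed
from the unrounded intermediate k; rounding happens only at presentation.

## Inverse estimator

Parameters a = (α, h′), h′ = h_H/(ρC_p), because the forward model depends
on the data only through that pair; h_H is recovered afterwards by
multiplying by a user-supplied ρC_p. Fitting operates on dimensionless
temperatures by default (σᵢ = 1 when unknown; known σ are rescaled by
1/|T₀ − T_eq| in the transform); a `scale="celsius"` option fits raw °C.

Each iteration builds the weighted normal equations M ΔA = C from a
central-difference Jacobian (relative step 10⁻³, absolute floor for a zero
parameter) and solves the damped system (M + λ diag M) ΔA = C, λ₀ = 10⁻³.
A step that does not increase χ² is accepted and λ is divided by 10;
otherwise λ is multiplied by 10 and the solve retried. Steps that would
drive a parameter non-positive are halved until feasible. Convergence:
both |Δaⱼ/aⱼ| < 10⁻⁵; cap 100 iterations. The damping is the standard
Levenberg–Marquardt safeguard: the pure Gauss–Newton normal equations can
diverge from distant starts such as α₀ = 10⁻⁷ against a truth of
1.43×10⁻⁷ with the wrong h′.

Uncertainty: covariance = inverse of the final *undamped* M, reported
unscaled by default; `rescale_covariance=True` multiplies by the reduced
chi-square χ²/(N−2) for users whose σᵢ are relative. Expanded
uncertainties are 2√(cov_jj) (coverage ≈ 95.4 % under Gaussian errors);
the parameter correlation cov₁₂/√(cov₁₁cov₂₂) is consistently negative
for center-curve designs — a faster-diffusing interior can be traded
against a less permeable surface. Goodness of fit: χ² = Σδ²/σ²,
RMSE = √(Σδ²/N), R² = 1 − SS_res/SS_tot, σ_fit = √(Σδ²/(N−2)).

Monte-Carlo calibration (tests): with known noise σ supplied, the
coverage of the 2σ intervals over 200 replicates of the default design
lies in [90 %, 99 %] for both parameters, and the covariance-derived
scatter matches the replicate-to-replicate scatter.

## Synthetic data generator

`carrot_chilling_design()` fixes the study conditions: R = 0.022 m,
L = 0.040 m, T₀ = 19.9 °C, T_eq = 3.5 °C, 49 samples equally spaced over
0–3600 s (75 s interval — one hour is the shortest horizon that brings the
center curve through the information-rich mid-transient at these Biot
numbers), truth α = 1.43×10⁻⁷ m²/s and h′ = 6.92/(1003·3918) m/s
(Bi₁ ≈ 0.271, Bi₂ ≈ 0.246). Noise is additive i.i.d. Gaussian on the
dimensionless scale by default (sd 0.005, a realistic ~0.1 °C thermocouple
scatter over a 16.4 °C span); a °C-scale option exists. The generator does
*not* emulate sensor lag, coolant-temperature fluctuation, probe placement
error, moisture loss or autocorrelated noise — passing recovery and
coverage tests therefore demonstrates correctness of the estimator under
the stated model, not robustness to those real-world effects.

## Known limitations

- Constant properties and constant T_eq: not suitable for processes with
  large ΔT (pasteurization) or fluctuating coolant temperature.
- Two fitted parameters only; lumped and first-kind forward evaluation is
  provided but their (single-parameter) inverse problems are not.
- The h_H-scale uncertainty is propagated from the h′ covariance by the
  ρC_p factor alone; uncertainty in ρ and C_p themselves is not folded in.
- The file dialect accepts '.' decimals only; locale decimal commas are
  rejected rather than guessed.
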