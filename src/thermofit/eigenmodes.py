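"""Eigenvalues and series coefficients for convectively cooled cylinders and slabs.

A solid finite cylinder cooling through its surface separates into the
product of two one-dimensional sub-problems: an infinite cylinder of the
same radius (radial factor, Bessel eigenfunctions) and an infinite slab --
"wall" -- of the same thickness (axial factor, cosine eigenfunctions).
Each sub-problem contributes an increasing eigenvalue sequence
``mu_1 < mu_2 < ...`` defined by a transcendental characteristic equation
parameterised by the Biot number ``Bi``, together with a series-coefficient
sequence ``A_1, A_2, ...`` for the center-symmetric initial condition.

Characteristic equations for a convective (Robin, "third kind") boundary::

    cylinder:  mu * J1(mu) = Bi * J0(mu)
    wall:      mu * sin(mu) = Bi * cos(mu)

In the limit ``Bi -> inf`` the surface temperature is prescribed ("first
kind" boundary) and the equations degenerate to ``J0(mu) = 0`` and
``cos(mu) = 0``.

Roots are found by bisection on analytically guaranteed brackets: cylinder
roots are isolated by the interlacing zeros of J0 and J1, wall roots by
``((m-1)*pi, (m-1)*pi + pi/2)``.  One sign change per bracket holds for
every ``Bi > 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

CYLINDER = "cylinder"
WALL = "wall"
_KINDS = (CYLINDER, WALL)

#: Bisection stops when the bracket width falls below this value.
DEFAULT_TOL = 1e-12
#: Number of series terms retained per sub-problem by default.
DEFAULT_N_TERMS = 200
#: Biot numbers above this are treated as infinite (first-kind boundary).
INFINITE_BIOT = 1e8


def _check_kind(kind: str) -> str:
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
    return kind


def is_infinite_biot(biot) -> bool:
    """True if *biot* requests the first-kind (prescribed-surface) limit."""
    if isinstance(biot, str):
        if biot == "infinite":
            return True
        raise ValueError(f"biot must be a number or 'infinite', got {biot!r}")
    return bool(np.isinf(biot)) or biot > INFINITE_BIOT


def characteristic_residual(kind: str, mu, biot):
    """Residual of the characteristic equation at *mu*.

    ``mu*J1(mu) - Bi*J0(mu)`` for the cylinder, ``mu*sin(mu) - Bi*cos(mu)``
    for the wall; zero exactly at the eigenvalues.
    """
    _check_kind(kind)
    mu = np.asarray(mu, dtype=float)
    if kind == CYLINDER:
        return mu * special.j1(mu) - biot * special.j0(mu)
    return mu * np.sin(mu) - biot * np.cos(mu)


def _bisect_all(f, lo, hi, tol):
    """Vectorised bisection on an array of brackets with a sign change each."""
    lo = np.array(lo, dtype=float)
    hi = np.array(hi, dtype=float)
    flo = f(lo)
    fhi = f(hi)
    bad = np.flatnonzero(np.sign(flo) * np.sign(fhi) >= 0)
    if bad.size:
        raise ArithmeticError(
            f"no sign change in bracket for root index {bad[0] + 1}: "
            f"[{lo[bad[0]]:.6g}, {hi[bad[0]]:.6g}]"
        )
    # ~45 halvings take a pi-wide bracket below 1e-12
    while np.any(hi - lo > tol):
        mid = 0.5 * (lo + hi)
        fmid = f(mid)
        go_right = np.sign(fmid) == np.sign(flo)
        lo = np.where(go_right, mid, lo)
        flo = np.where(go_right, fmid, flo)
        hi = np.where(go_right, hi, mid)
    return 0.5 * (lo + hi)


def _first_kind_roots(kind: str, n_roots: int) -> np.ndarray:
    if kind == CYLINDER:
        return special.jn_zeros(0, n_roots)
    return (2.0 * np.arange(1, n_roots + 1) - 1.0) * np.pi / 2.0


def find_roots(kind: str, biot, n_roots: int = DEFAULT_N_TERMS,
               tol: float = DEFAULT_TOL) -> np.ndarray:
    """First *n_roots* eigenvalues of the characteristic equation.

    Parameters
    ----------
    kind : {"cylinder", "wall"}
        Which sub-problem the eigenvalues belong to.
    biot : float or "infinite"
        Biot number of the sub-problem (``> 0``), or the first-kind limit.
    n_roots : int
        How many leading roots to return.
    tol : float
        Bisection stops when the bracket width falls below ``tol``.

    Returns
    -------
    numpy.ndarray
        Strictly increasing positive eigenvalues ``mu_1 .. mu_n``.
    """
    _check_kind(kind)
    if n_roots < 1:
        raise ValueError("n_roots must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if is_infinite_biot(biot):
        return _first_kind_roots(kind, n_roots)
    biot = float(biot)
    if biot < 0:
        raise ValueError(f"biot must be >= 0, got {biot}")
    if biot == 0:
        raise ValueError(
            "biot = 0 degenerates the convective eigenproblem (no cooling); "
            "use a positive Biot number"
        )

    if kind == CYLINDER:
        # root n lies between the (n-1)-th zero of J1 (0 counts as the 0th)
        # and the n-th zero of J0
        hi = special.jn_zeros(0, n_roots)
        lo = np.concatenate(([0.0], special.jn_zeros(1, n_roots - 1))) if n_roots > 1 \
            else np.array([0.0])
    else:
        m = np.arange(1, n_roots + 1)
        lo = (m - 1) * np.pi
        hi = (m - 1) * np.pi + np.pi / 2.0

    return _bisect_all(lambda mu: characteristic_residual(kind, mu, biot), lo, hi, tol)


def first_kind_coefficients(kind: str, n_terms: int):
    """Roots and coefficients for the prescribed-surface (first kind) boundary.

    Cylinder: roots are the zeros of J0 with ``A_n = 2/(mu_n*J1(mu_n))``.
    Wall: roots are the odd multiples of pi/2 with
    ``A_m = (-1)**(m+1) * 2/mu_m``.
    """
    _check_kind(kind)
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    roots = _first_kind_roots(kind, n_terms)
    if kind == CYLINDER:
        coeffs = 2.0 / (roots * special.j1(roots))
    else:
        m = np.arange(1, n_terms + 1)
        coeffs = (-1.0) ** (m + 1) * 2.0 / roots
    return roots, coeffs


def third_kind_coefficients(kind: str, roots, biot) -> np.ndarray:
    """Series coefficients for the convective (third kind) boundary.

    Cylinder: ``A_n = 2*Bi / (J0(mu_n)*(Bi**2 + mu_n**2))``.
    Wall: ``A_m = (-1)**(m+1) * 2*Bi*sqrt(Bi**2 + mu_m**2)
    / (mu_m*(Bi**2 + Bi + mu_m**2))``.

    The supplied roots must solve the characteristic equation for this
    (kind, Bi); a residual check guards against mismatched inputs.
    """
    _check_kind(kind)
    roots = np.asarray(roots, dtype=float)
    if is_infinite_biot(biot):
        _, coeffs = first_kind_coefficients(kind, len(roots))
        return coeffs
    biot = float(biot)
    if biot <= 0:
        raise ValueError(f"biot must be > 0 for the convective boundary, got {biot}")
    resid = characteristic_residual(kind, roots, biot)
    scale = (1.0 + biot) * (1.0 + roots)
    if np.any(np.abs(resid) > 1e-8 * scale):
        i = int(np.argmax(np.abs(resid) / scale))
        raise ValueError(
            f"root {i + 1} ({roots[i]:.6g}) does not solve the {kind} "
            f"characteristic equation at Bi={biot:.6g} (residual {resid[i]:.3g})"
        )
    if kind == CYLINDER:
        return 2.0 * biot / (special.j0(roots) * (biot**2 + roots**2))
    m = np.arange(1, len(roots) + 1)
    return ((-1.0) ** (m + 1) * 2.0 * biot * np.sqrt(biot**2 + roots**2)
            / (roots * (biot**2 + biot + roots**2)))


@dataclass(frozen=True)
class EigenExpansion:
    """Eigenvalues and coefficients of one 1D sub-problem at a fixed Biot number.

    Attributes
    ----------
    kind : {"cylinder", "wall"}
    biot : float
        Biot number; ``inf`` marks the first-kind (prescribed surface) limit.
    roots : numpy.ndarray
        Strictly increasing eigenvalues.
    coeffs : numpy.ndarray
        Matching series coefficients.
    """

    kind: str
    biot: float
    roots: np.ndarray = field(repr=False)
    coeffs: np.ndarray = field(repr=False)

    @property
    def n_terms(self) -> int:
        return len(self.roots)

    @classmethod
    def third_kind(cls, kind: str, biot, n_terms: int = DEFAULT_N_TERMS,
                   tol: float = DEFAULT_TOL) -> "EigenExpansion":
        roots = find_roots(kind, biot, n_terms, tol)
        coeffs = third_kind_coefficients(kind, roots, biot)
        b = np.inf if is_infinite_biot(biot) else float(biot)
        return cls(kind=kind, biot=b, roots=roots, coeffs=coeffs)

    @classmethod
    def first_kind(cls, kind: str, n_terms: int = DEFAULT_N_TERMS) -> "EigenExpansion":
        roots, coeffs = first_kind_coefficients(kind, n_terms)
        return cls(kind=kind, biot=np.inf, roots=roots, coeffs=coeffs)
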