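"""Shared analytic machinery for the stationary Fokker-Planck solutions.

Both noise models reduce to the same one-dimensional problem: a stationary
density of the zero-flux form

    Pst(x) = N / B(x) * exp( Integral A(x)/B(x) dx )

with a quadratic diffusion ``B(x) = D x^2 + 2 lam sqrt(D Q) x + Q`` and a
drift ``A(x) = a x - b x ln x + D x + lam sqrt(D Q)``.  The white-noise model
uses (a, b) = (alpha, beta) directly; the colored-noise model enters through
the effective parameters (alpha(1+tau*beta), beta(1+tau*beta)) -- see
:mod:`gompertz_sde.spd_colored`.

The integral of A/B is not elementary because of the x ln x term.  The
closed-form branch replaces ln x by its second-order Taylor polynomial about
x = 1, i.e. ``x ln x -> p(x) = -x^3/2 + 2 x^2 - 3 x/2``; with that
substitution A/B is rational and integrates to a polynomial plus logarithmic
plus arctangent (|lam| < 1) or inverse (|lam| = 1) terms.  The coefficient
sets implemented here have been verified symbolically against the defining
integral (see the test suite); the quadrature branch keeps the exact
logarithm and is the reference everywhere accuracy matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_simpson
from scipy.interpolate import PchipInterpolator

__all__ = [
    "ClosedFormCoefficients",
    "ClosedFormUnsupported",
    "diffusion",
    "drift_exact",
    "drift_poly",
    "xlogx_poly",
    "coefficients",
    "log_density_closed",
    "potential_closed",
    "potential_quadrature_interpolant",
    "log_density_quadrature",
]


class ClosedFormUnsupported(ValueError):
    """The closed-form branch does not exist for these parameters."""


def _xlogx(x: np.ndarray) -> np.ndarray:
    """x*ln(x) with its limit value 0 at x = 0."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(x > 0, x * np.log(np.where(x > 0, x, 1.0)), 0.0)


def xlogx_poly(x) -> np.ndarray:
    """Cubic substitute for x*ln(x): x times the 2nd-order Taylor of ln about 1."""
    x = np.asarray(x, dtype=float)
    return -0.5 * x**3 + 2.0 * x**2 - 1.5 * x


def diffusion(x, a, b, D, Q, lam):
    x = np.asarray(x, dtype=float)
    return D * x * x + 2.0 * lam * math.sqrt(D * Q) * x + Q


def drift_exact(x, a, b, D, Q, lam):
    x = np.asarray(x, dtype=float)
    return a * x - b * _xlogx(x) + D * x + lam * math.sqrt(D * Q)


def drift_poly(x, a, b, D, Q, lam):
    x = np.asarray(x, dtype=float)
    return a * x - b * xlogx_poly(x) + D * x + lam * math.sqrt(D * Q)


@dataclass(frozen=True)
class ClosedFormCoefficients:
    """Constants of the closed-form antiderivative of A_poly/B.

    On the subcritical branch (|lam| < 1):

        Integral A_poly/B dx = C*ln(B) + f_quad*x^2 + f_lin*x
                               + (E/s) * arctan((D x + lam sqrt(DQ)) / s),
        s = sqrt((1 - lam^2) D Q).

    On the critical branch (|lam| = 1), with u = sqrt(D) x + sign(lam) sqrt(Q)
    (so B = u^2):

        Integral A_poly/B dx = f_quad*x^2 + f_lin*x + f_const
                               + C*ln|u| - E/u.
    """

    branch: str  # "subcritical" | "critical"
    f_quad: float
    f_lin: float
    C: float
    E: float
    f_const: float = 0.0

    def antiderivative(self, x, D, Q, lam):
        """Evaluate Integral A_poly/B dx at x (up to its integration constant)."""
        x = np.asarray(x, dtype=float)
        poly = self.f_quad * x * x + self.f_lin * x + self.f_const
        r = math.sqrt(D * Q)
        if self.branch == "subcritical":
            s = math.sqrt((1.0 - lam * lam) * D * Q)
            B = D * x * x + 2.0 * lam * r * x + Q
            return self.C * np.log(B) + poly + (self.E / s) * np.arctan((D * x + lam * r) / s)
        u = math.sqrt(D) * x + math.copysign(math.sqrt(Q), lam)
        return poly + self.C * np.log(np.abs(u)) - self.E / u


def coefficients(a, b, D, Q, lam) -> ClosedFormCoefficients:
    """Closed-form constants for the effective parameter set (a, b, D, Q, lam)."""
    if D <= 0:
        raise ClosedFormUnsupported(
            "closed form requires multiplicative noise D > 0; use the quadrature method"
        )
    if abs(lam) > 1:
        raise ValueError("|lam| must be <= 1")
    r = math.sqrt(D * Q)
    if abs(lam) == 1.0:
        sgn = math.copysign(1.0, lam)
        sq = math.sqrt(Q)
        f_quad = b / (4.0 * D)
        f_lin = -(2.0 * b / D + sgn * b * sq / D**1.5)
        f_const = -1.25 * Q * b / D**2 - 2.0 * sgn * sq * b / D**1.5
        C = 1.0 + a / D + 1.5 * b / D + 1.5 * Q * b / D**2 + 4.0 * sgn * sq * b / D**1.5
        E = -sgn * (sq * a / D + 1.5 * sq * b / D + 0.5 * Q**1.5 * b / D**2) - 2.0 * Q * b / D**1.5
        return ClosedFormCoefficients("critical", f_quad, f_lin, C, E, f_const)
    f_quad = b / (4.0 * D)
    f_lin = -(2.0 * b / D + lam * b * r / D**2)
    C = (
        a / (2.0 * D)
        + 0.75 * b / D
        + 2.0 * lam * b * r / D**2
        + (4.0 * lam * lam - 1.0) * b * Q / (4.0 * D**2)
        + 0.5
    )
    E = (
        (2.0 - 4.0 * lam * lam) * b * Q / D
        - (2.0 * a + 3.0 * b) * lam * r / (2.0 * D)
        + (3.0 - 4.0 * lam * lam) * lam * b * Q * r / (2.0 * D**2)
    )
    return ClosedFormCoefficients("subcritical", f_quad, f_lin, C, E)


def log_density_closed(x, a, b, D, Q, lam):
    """Unnormalized log of the closed-form stationary density.

    log Pst = -ln B + Integral A_poly/B dx  (up to the normalization constant).
    """
    cf = coefficients(a, b, D, Q, lam)
    x = np.asarray(x, dtype=float)
    B = diffusion(x, a, b, D, Q, lam)
    return cf.antiderivative(x, D, Q, lam) - np.log(B)


def potential_closed(x, a, b, D, Q, lam):
    """Modified potential Phi(x) = -Integral A_poly/B dx (closed form)."""
    cf = coefficients(a, b, D, Q, lam)
    return -cf.antiderivative(np.asarray(x, dtype=float), D, Q, lam)


#: Boundary between the linear head and the geometric tail of wide grids.
_GRID_KNEE = 8.0


def support_grid(lo: float, hi: float, n: int) -> np.ndarray:
    """Evaluation grid: linear up to the knee, geometric beyond.

    The stationary densities live on log scale far to the right (tails decay
    like exp(-b (ln x)^2 / 2D)), so wide supports need geometric spacing there
    while the structure near the origin needs linear resolution.
    """
    if hi <= _GRID_KNEE or lo >= _GRID_KNEE:
        return np.linspace(lo, hi, n)
    head = np.linspace(lo, _GRID_KNEE, n // 2)
    tail = np.geomspace(_GRID_KNEE, hi, n - n // 2 + 1)[1:]
    return np.concatenate([head, tail])


def _dense_grid(lo: float, hi: float, n: int) -> np.ndarray:
    return support_grid(lo, hi, n)


def potential_quadrature_interpolant(a, b, D, Q, lam, lo, hi, x_ref=1.0, n=4001):
    """PCHIP interpolant of Phi(x) = -Integral_{x_ref}^{x} A_exact/B on [lo, hi].

    The inner integral uses the exact x ln x drift; the cumulative integral is
    accumulated on a dense grid with composite Simpson quadrature and then
    interpolated monotonically in each panel, which keeps pointwise errors far
    below the 1e-6 tolerances used downstream.
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    grid = _dense_grid(lo, hi, n)
    ratio = drift_exact(grid, a, b, D, Q, lam) / diffusion(grid, a, b, D, Q, lam)
    I = np.concatenate([[0.0], cumulative_simpson(ratio, x=grid)])
    interp = PchipInterpolator(grid, I, extrapolate=False)
    offset = 0.0
    if lo <= x_ref <= hi:
        offset = float(interp(x_ref))
    return PchipInterpolator(grid, -(I - offset), extrapolate=False)


def log_density_quadrature(a, b, D, Q, lam, lo, hi, x_ref=1.0, n=4001):
    """Callable unnormalized log-density -ln B - Phi_quadrature on [lo, hi]."""
    phi = potential_quadrature_interpolant(a, b, D, Q, lam, lo, hi, x_ref=x_ref, n=n)

    def log_unnorm(x):
        x = np.asarray(x, dtype=float)
        return -np.log(diffusion(x, a, b, D, Q, lam)) - phi(x)

    return log_unnorm
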