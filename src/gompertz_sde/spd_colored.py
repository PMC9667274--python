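"""Stationary density for the colored-noise model (unified colored-noise
approximation, UCNA).

The multiplicative noise is an Ornstein-Uhlenbeck process with intensity D2
and correlation time tau (autocovariance (D2/tau) exp(-|t-s|/tau)); the
additive noise stays white with intensity Q and cross-correlation lambda2.
The UCNA reduces the joint (x, xi) dynamics to a one-dimensional Markov
diffusion whose Fokker-Planck drift and diffusion are

    G(x) = (alpha*x - beta*x*ln x)/(1+tau*beta)
           + (D2*x + lambda2*sqrt(D2*Q))/(1+tau*beta)^2,
    H(x) = (D2*x^2 + 2*lambda2*sqrt(D2*Q)*x + Q)/(1+tau*beta)^2.

Because G/H = A~/B~ with the *effective* rates alpha~ = alpha(1+tau*beta)
and beta~ = beta(1+tau*beta) (noise parameters unchanged), the entire
white-noise machinery applies verbatim after that substitution; the
(1+tau*beta) prefactor of the density is absorbed into the normalization.
At tau = 0 every quantity reduces exactly to its white-noise counterpart
with D1 -> D2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import _closedform as cf
from .density import NormalizedDensity
from .model_core import GompertzParams
from .spd_white import DEFAULT_DOMAIN

__all__ = [
    "ColoredNoiseParams",
    "ExtremumResult",
    "drift_G",
    "diffusion_H",
    "closed_form_coefficients_colored",
    "modified_potential_colored",
    "spd_colored",
    "spd_extremum",
    "extremum_equation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColoredNoiseParams:
    """Colored (multiplicative) noise intensity D2, additive intensity Q,
    cross-correlation lambda2 and correlation time tau."""

    D2: float
    Q: float
    lambda2: float = 0.0
    tau: float = 0.0

    def __post_init__(self) -> None:
        if not (self.D2 >= 0 and math.isfinite(self.D2)):
            raise ValueError("D2 must be >= 0")
        if not (self.Q >= 0 and math.isfinite(self.Q)):
            raise ValueError("Q must be >= 0")
        if abs(self.lambda2) > 1:
            raise ValueError("|lambda2| must be <= 1")
        if not (self.tau >= 0 and math.isfinite(self.tau)):
            raise ValueError("tau must be >= 0")

    def scale(self, gp: GompertzParams) -> float:
        """UCNA scale factor 1 + tau*beta (> 0 for any valid parameters)."""
        return 1.0 + self.tau * gp.beta

    def as_effective(self, gp: GompertzParams) -> tuple:
        """Effective (a, b, D, Q, lam) with a, b scaled by (1 + tau*beta)."""
        s = self.scale(gp)
        if self.tau * gp.beta > 1.0:
            logger.warning(
                "tau*beta = %.3g > 1: the colored-noise reduction is used far "
                "outside the small-correlation-time regime", self.tau * gp.beta,
            )
        return (gp.alpha * s, gp.beta * s, self.D2, self.Q, self.lambda2)


def drift_G(x, gp: GompertzParams, cp: ColoredNoiseParams):
    """Effective drift G(x) of the reduced one-dimensional diffusion."""
    s = cp.scale(gp)
    return cf.drift_exact(x, *cp.as_effective(gp)) / (s * s)


def diffusion_H(x, gp: GompertzParams, cp: ColoredNoiseParams):
    """Effective diffusion H(x) = B(x) / (1 + tau*beta)^2."""
    s = cp.scale(gp)
    return cf.diffusion(x, *cp.as_effective(gp)) / (s * s)


def closed_form_coefficients_colored(gp: GompertzParams, cp: ColoredNoiseParams):
    """Closed-form constants (the colored analogues of the white-noise set)."""
    return cf.coefficients(*cp.as_effective(gp))


def modified_potential_colored(x, gp: GompertzParams, cp: ColoredNoiseParams,
                               method: str = "closed_form", domain=DEFAULT_DOMAIN,
                               x_ref: float = 1.0):
    """Modified potential Phi2(x) = -Integral G/H dx (up to a constant).

    G/H equals the effective-parameter drift-to-diffusion ratio, so Phi2 is
    Phi1 evaluated at the effective rates; at tau = 0 it coincides pointwise
    with the white-noise potential under D1 -> D2.
    """
    eff = cp.as_effective(gp)
    if method == "closed_form":
        return cf.potential_closed(x, *eff)
    if method == "quadrature":
        interp = cf.potential_quadrature_interpolant(*eff, domain[0], domain[1], x_ref=x_ref)
        out = interp(np.asarray(x, dtype=float))
        return float(out) if np.ndim(out) == 0 else out
    raise ValueError("method must be 'closed_form' or 'quadrature'")


def spd_colored(gp: GompertzParams, cp: ColoredNoiseParams, method: str = "closed_form",
                domain=DEFAULT_DOMAIN, grid_n: int = 2001) -> NormalizedDensity:
    """Stationary density of the reduced diffusion, normalized over ``domain``."""
    eff = cp.as_effective(gp)
    params = {"alpha": gp.alpha, "beta": gp.beta, "D2": cp.D2, "Q": cp.Q,
              "lambda2": cp.lambda2, "tau": cp.tau, "model": "colored"}
    if method == "closed_form":
        def log_unnorm(x, _eff=eff):
            return cf.log_density_closed(x, *_eff)
    elif method == "quadrature":
        log_unnorm = cf.log_density_quadrature(*eff, domain[0], domain[1],
                                               n=max(4001, 2 * grid_n))
    else:
        raise ValueError("method must be 'closed_form' or 'quadrature'")
    return NormalizedDensity(log_unnorm=log_unnorm, domain=tuple(map(float, domain)),
                             method=method, params=params, grid_n=grid_n)


@dataclass(frozen=True)
class ExtremumResult:
    """A root of the stationary-density extremum condition."""

    xm: float
    residual: float
    variant: str


def extremum_equation(x, gp: GompertzParams, cp: ColoredNoiseParams,
                      variant: str = "derived"):
    """The extremum condition whose roots locate the stationary-density modes.

    variant="derived": G(x) - H'(x), which vanishes exactly at every interior
    extremum of the stationary density (zero-flux condition).
    variant="printed": the same expression with the sign of the
    lambda2*sqrt(D2*Q) term flipped; exposed for comparison because the
    reported extremum trends in additive intensity and cross-correlation
    follow this variant (see docs/methods.md).
    """
    x = np.asarray(x, dtype=float)
    s = cp.scale(gp)
    r = math.sqrt(cp.D2 * cp.Q)
    with np.errstate(divide="ignore", invalid="ignore"):
        xlx = np.where(x > 0, x * np.log(np.where(x > 0, x, 1.0)), 0.0)
    det = (gp.alpha * x - gp.beta * xlx) / s
    sign = -1.0 if variant == "derived" else 1.0
    if variant not in ("derived", "printed"):
        raise ValueError("variant must be 'derived' or 'printed'")
    out = det - cp.D2 * x / (s * s) + sign * cp.lambda2 * r / (s * s)
    return float(out) if out.ndim == 0 else out


def spd_extremum(gp: GompertzParams, cp: ColoredNoiseParams,
                 bracket=(1e-6, 20.0), variant: str = "derived") -> ExtremumResult:
    """Bracketed root of the extremum condition.

    At lambda2 = 0 the equation has the closed-form solution
    xm = exp[(alpha - D2/(1+tau*beta)) / beta].
    """
    lo, hi = bracket
    f = lambda x: extremum_equation(x, gp, cp, variant=variant)
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"extremum equation has no sign change on [{lo}, {hi}] "
            f"(f(lo)={flo:.3g}, f(hi)={fhi:.3g}); widen the bracket"
        )
    xm = brentq(f, lo, hi, xtol=1e-14, rtol=1e-15)
    return ExtremumResult(xm=float(xm), residual=abs(f(xm)), variant=variant)
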