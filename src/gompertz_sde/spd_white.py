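"""Stationary density for the white-noise Langevin model.

The growth law is driven by a multiplicative Gaussian white noise of
intensity D1 (entering as ``x * eps(t)``) and an additive Gaussian white
noise of intensity Q, cross-correlated with coefficient lambda1.  The
associated Fokker-Planck equation has drift and diffusion

    A(x) = alpha*x - beta*x*ln x + D1*x + lambda1*sqrt(D1*Q),
    B(x) = D1*x^2 + 2*lambda1*sqrt(D1*Q)*x + Q,

and the stationary solution Pst = N/B * exp(Integral A/B).  Two evaluation
methods are provided: "closed_form" (polynomial approximation of x ln x,
elementary antiderivative, valid on a truncation window) and "quadrature"
(exact logarithm, numerically integrated; normalizable tails).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _closedform as cf
from .density import NormalizedDensity
from .model_core import GompertzParams

__all__ = [
    "WhiteNoiseParams",
    "ClosedFormCoefficients",
    "drift_A",
    "diffusion_B",
    "closed_form_coefficients",
    "modified_potential_white",
    "spd_white",
    "DEFAULT_DOMAIN",
]

ClosedFormCoefficients = cf.ClosedFormCoefficients

#: Default truncation window for closed-form normalization and moment
#: integrals; covers the plotting range of the stationary-density figures.
DEFAULT_DOMAIN = (0.0, 10.0)


@dataclass(frozen=True)
class WhiteNoiseParams:
    """Intensities of the two white noises and their cross-correlation.

    D1 is the multiplicative intensity, Q the additive intensity and
    lambda1 in [-1, 1] the cross-correlation coefficient.  For |lambda1| < 1
    and Q > 0 the diffusion B(x) is strictly positive for all x >= 0.
    """

    D1: float
    Q: float
    lambda1: float = 0.0

    def __post_init__(self) -> None:
        if not (self.D1 >= 0 and math.isfinite(self.D1)):
            raise ValueError("D1 must be >= 0")
        if not (self.Q >= 0 and math.isfinite(self.Q)):
            raise ValueError("Q must be >= 0")
        if abs(self.lambda1) > 1:
            raise ValueError("|lambda1| must be <= 1")

    def as_effective(self, gp: GompertzParams) -> tuple:
        return (gp.alpha, gp.beta, self.D1, self.Q, self.lambda1)


def drift_A(x, gp: GompertzParams, wp: WhiteNoiseParams):
    """Fokker-Planck drift A(x); x >= 0 (x ln x takes its limit 0 at 0)."""
    return cf.drift_exact(x, *wp.as_effective(gp))


def diffusion_B(x, gp: GompertzParams, wp: WhiteNoiseParams):
    """Fokker-Planck diffusion B(x) = D1 x^2 + 2 lambda1 sqrt(D1 Q) x + Q."""
    return cf.diffusion(x, *wp.as_effective(gp))


def closed_form_coefficients(gp: GompertzParams, wp: WhiteNoiseParams) -> ClosedFormCoefficients:
    """Constants of the elementary antiderivative of A_poly/B.

    Raises :class:`~gompertz_sde._closedform.ClosedFormUnsupported` when
    D1 = 0 (the closed form assumes multiplicative noise; use quadrature).
    """
    return cf.coefficients(*wp.as_effective(gp))


def modified_potential_white(x, gp: GompertzParams, wp: WhiteNoiseParams,
                             method: str = "closed_form", domain=DEFAULT_DOMAIN,
                             x_ref: float = 1.0):
    """Modified potential Phi1(x) = -Integral A/B dx (defined up to a constant).

    method="closed_form" uses the elementary antiderivative (polynomial
    x ln x substitute); method="quadrature" integrates the exact A/B from
    ``x_ref`` numerically.
    """
    eff = wp.as_effective(gp)
    if method == "closed_form":
        return cf.potential_closed(x, *eff)
    if method == "quadrature":
        interp = cf.potential_quadrature_interpolant(*eff, domain[0], domain[1], x_ref=x_ref)
        out = interp(np.asarray(x, dtype=float))
        return float(out) if np.ndim(out) == 0 else out
    raise ValueError("method must be 'closed_form' or 'quadrature'")


def spd_white(gp: GompertzParams, wp: WhiteNoiseParams, method: str = "closed_form",
              domain=DEFAULT_DOMAIN, grid_n: int = 2001) -> NormalizedDensity:
    """Stationary probability density, normalized over ``domain``."""
    eff = wp.as_effective(gp)
    params = {"alpha": gp.alpha, "beta": gp.beta, "D1": wp.D1, "Q": wp.Q,
              "lambda1": wp.lambda1, "model": "white"}
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
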