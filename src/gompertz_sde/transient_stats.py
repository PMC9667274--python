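"""First-passage times and stationary moment statistics.

Mean first-passage time (MFPT) from the unstable start state xu = 1 up to the
stable state xs = exp(alpha/beta) of the reduced colored-noise diffusion:

* ``mfpt_integral`` evaluates the exact double integral for a diffusion with
  reflecting lower boundary,
      T = Integral_{xu}^{xs} dx / (H(x) Pst(x)) * Integral_0^x Pst(y) dy,
  by nested quadrature against a normalized stationary density.
* ``mfpt_kramers`` evaluates the steepest-descent (Kramers) approximation
      T ~ 2*pi / sqrt(|V''(xu) V''(xs)|) * exp(Phi2(xu) - Phi2(xs)),
  with V''(1) = beta - alpha and V''(xs) = beta, so the prefactor is
  2*pi / sqrt(|beta^2 - alpha*beta|).  The literal reading of the printed
  prefactor (no square root) is available behind ``sqrt_prefactor=False``.

Stationary statistics of the tumor-cell number from a normalized density:
mean <x>, normalized variance sigma2 = <x^2>/<x>^2 - 1 and normalized
skewness sigma3 = <x^3>/<x>^3 - 3*sigma2 - 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace
from typing import Optional


import pandas as pd
from scipy.integrate import quad, simpson

from .density import NormalizedDensity
from .model_core import GompertzParams
from .spd_colored import (
    ColoredNoiseParams,
    diffusion_H,
    modified_potential_colored,
    spd_colored,
    spd_extremum,
)
from .spd_white import DEFAULT_DOMAIN

__all__ = [
    "MFPTResult",
    "MomentSummary",
    "mfpt_integral",
    "mfpt_kramers",
    "stationary_moment",
    "normalized_variance",
    "normalized_skewness",
    "moment_summary",
    "wide_support_domain",
    "sweep",
]


@dataclass(frozen=True)
class MFPTResult:
    T: float
    lnT: float
    method: str
    x_start: float
    x_target: float
    params: dict

    def __post_init__(self) -> None:
        if self.T < 0:
            raise ValueError("mean first-passage time must be >= 0")


@dataclass(frozen=True)
class MomentSummary:
    mean: float
    variance_norm: float
    skewness_norm: float
    raw_second: float
    raw_third: float
    domain: tuple
    method: str


def wide_support_domain(gp: GompertzParams, cp: ColoredNoiseParams,
                        k: int = 3, cap: float = 1e15) -> tuple:
    """A truncation window wide enough that moments up to order ``k`` are
    effectively untruncated.

    The stationary log-state is approximately Gaussian with variance
    sigma_u^2 = D2 / (beta (1 + tau*beta)) around alpha/beta, and the
    integrand of the k-th moment peaks near ln x = alpha/beta + k sigma_u^2;
    the window extends several sigma_u beyond that.
    """
    su2 = cp.D2 / (gp.beta * (1.0 + cp.tau * gp.beta)) + 1e-12
    hi = math.exp(gp.alpha / gp.beta + (k + 0.5) * su2 + 8.0 * math.sqrt(su2))
    return (0.0, float(min(max(hi, 50.0), cap)))


def _grid_moments(density: NormalizedDensity, orders=(1, 2, 3)) -> dict:
    """Raw moments by composite Simpson on the density's evaluation grid.

    Using one shared quadrature rule for every integrand makes the two
    algebraic forms of the normalized variance agree to machine precision.
    """
    x = density._grid
    pdf = density.evaluate(x)
    z = simpson(pdf, x=x)
    return {k: float(simpson(x**k * pdf, x=x) / z) for k in orders} | {0: float(z)}


def mfpt_integral(gp: GompertzParams, cp: ColoredNoiseParams,
                  density: Optional[NormalizedDensity] = None,
                  x_start: Optional[float] = None,
                  x_target: Optional[float] = None) -> MFPTResult:
    """Nested-quadrature MFPT of the reduced diffusion (reflecting at 0).

    ``density`` defaults to the quadrature-method stationary density on a
    window wide enough to contain the passage range; x_start defaults to the
    unstable state 1 and x_target to the stable state exp(alpha/beta).
    """
    if x_start is None:
        x_start = 1.0
    if x_target is None:
        x_target = gp.stable_state
    if density is None:
        hi = max(DEFAULT_DOMAIN[1], 3.0 * x_target)
        density = spd_colored(gp, cp, method="quadrature", domain=(0.0, hi))
    lo, hi = density.domain
    if not (lo <= x_start <= hi and lo <= x_target <= hi):
        raise ValueError("passage range must lie within the density domain")
    if x_start > x_target:
        raise ValueError("upward passage requires x_start <= x_target")
    params = dict(density.params)
    if x_start == x_target:
        return MFPTResult(T=0.0, lnT=-math.inf, method="integral",
                          x_start=x_start, x_target=x_target, params=params)

    def outer(x):
        p = float(density.evaluate(x))
        if p <= 0:
            raise ZeroDivisionError(
                f"stationary density vanishes at x = {x:.6g} inside the passage range"
            )
        return float(density.cdf(x)) / (float(diffusion_H(x, gp, cp)) * p)

    T, _ = quad(outer, x_start, x_target, limit=200, epsrel=1e-8)
    return MFPTResult(T=T, lnT=math.log(T), method="integral",
                      x_start=x_start, x_target=x_target, params=params)


def mfpt_kramers(gp: GompertzParams, cp: ColoredNoiseParams,
                 sqrt_prefactor: bool = True) -> MFPTResult:
    """Kramers steepest-descent MFPT from xu = 1 to xs = exp(alpha/beta).

    Uses the closed-form modified potential so the integration constants
    cancel exactly in the difference Phi2(1) - Phi2(xs).  The curvature
    prefactor 2*pi/sqrt(|beta^2 - alpha*beta|) requires alpha != beta.
    """
    if gp.alpha == gp.beta:
        raise ValueError("Kramers prefactor vanishes at alpha == beta "
                         "(|V''(1)| = |beta - alpha| = 0)")
    xs = gp.stable_state
    curv = abs(gp.beta**2 - gp.alpha * gp.beta)
    pref = 2.0 * math.pi / math.sqrt(curv) if sqrt_prefactor else 2.0 * math.pi * curv
    dphi = float(modified_potential_colored(1.0, gp, cp, method="closed_form")) - float(
        modified_potential_colored(xs, gp, cp, method="closed_form"))
    T = pref * math.exp(dphi)
    params = {"alpha": gp.alpha, "beta": gp.beta, "D2": cp.D2, "Q": cp.Q,
              "lambda2": cp.lambda2, "tau": cp.tau,
              "sqrt_prefactor": sqrt_prefactor}
    return MFPTResult(T=T, lnT=math.log(T), method="kramers",
                      x_start=1.0, x_target=xs, params=params)


def _check_normalized(moments: dict) -> None:
    if abs(moments[0] - 1.0) > 1e-4:
        raise ValueError(f"density is not normalized (integral = {moments[0]:.6g})")


def stationary_moment(density: NormalizedDensity, k: int) -> float:
    """Raw moment <x^k>, k in {1, 2, 3}, over the density's domain."""
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    m = _grid_moments(density, orders=(k,))
    _check_normalized(m)
    return m[k]


def normalized_variance(density: NormalizedDensity) -> float:
    """sigma2 = <(x - <x>)^2>/<x>^2 = <x^2>/<x>^2 - 1 (both forms computed)."""
    m = _grid_moments(density, orders=(1, 2))
    _check_normalized(m)
    m1, m2 = m[1], m[2]
    if m1 <= 0:
        raise ValueError("mean must be positive")
    form_ratio = m2 / m1**2 - 1.0
    x = density._grid
    pdf = density.evaluate(x)
    central = float(simpson((x - m1) ** 2 * pdf, x=x) / simpson(pdf, x=x))
    form_central = central / m1**2
    if abs(form_ratio - form_central) > 1e-10 * max(1.0, abs(form_ratio)):
        raise AssertionError(
            f"the two variance forms disagree: {form_ratio!r} vs {form_central!r}"
        )
    return form_ratio


def normalized_skewness(density: NormalizedDensity) -> float:
    """sigma3 = <x^3>/<x>^3 - 3*sigma2 - 1."""
    m = _grid_moments(density)
    _check_normalized(m)
    if m[1] <= 0:
        raise ValueError("mean must be positive")
    return m[3] / m[1]**3 - 3.0 * normalized_variance(density) - 1.0


def moment_summary(density: NormalizedDensity) -> MomentSummary:
    m = _grid_moments(density)
    _check_normalized(m)
    s2 = normalized_variance(density)
    return MomentSummary(mean=m[1], variance_norm=s2,
                         skewness_norm=m[3] / m[1]**3 - 3.0 * s2 - 1.0,
                         raw_second=m[2], raw_third=m[3],
                         domain=density.domain, method=density.method)


_QUANTITIES = ("xm", "lnT_kramers", "lnT_integral", "mean", "variance_norm",
               "skewness_norm")
_PARAMETERS = ("alpha", "beta", "D2", "Q", "lambda2", "tau")


def _evaluate_quantity(quantity: str, gp: GompertzParams, cp: ColoredNoiseParams,
                       domain, density_method: str, extremum_variant: str,
                       bracket) -> float:
    if quantity == "xm":
        return spd_extremum(gp, cp, bracket=bracket, variant=extremum_variant).xm
    if quantity == "lnT_kramers":
        return mfpt_kramers(gp, cp).lnT
    if quantity == "lnT_integral":
        return mfpt_integral(gp, cp).lnT
    grid_n = 4001
    if isinstance(domain, str):
        if domain != "wide":
            raise ValueError("domain must be an interval or 'wide'")
        domain = wide_support_domain(gp, cp)
        grid_n = 8001
    density = spd_colored(gp, cp, method=density_method, domain=domain, grid_n=grid_n)
    if quantity == "mean":
        return stationary_moment(density, 1)
    if quantity == "variance_norm":
        return normalized_variance(density)
    if quantity == "skewness_norm":
        return normalized_skewness(density)
    raise ValueError(f"unknown quantity {quantity!r}; valid: {_QUANTITIES}")


def sweep(quantity: str, parameter: str, values, gp: GompertzParams,
          cp: ColoredNoiseParams, domain=DEFAULT_DOMAIN,
          density_method: str = "quadrature", extremum_variant: str = "derived",
          bracket=(1e-6, 20.0)) -> pd.DataFrame:
    """Evaluate ``quantity`` across ``values`` of ``parameter``, all else fixed.

    ``domain`` applies to the moment quantities: an interval for truncated
    moments (default: the shared plotting window) or the string "wide" for an
    adaptive effectively-untruncated support.  Returns a tidy two-column
    table ``<parameter>, <quantity>``.
    """
    if quantity not in _QUANTITIES:
        raise ValueError(f"quantity must be one of {_QUANTITIES}, got {quantity!r}")
    if parameter not in _PARAMETERS:
        raise ValueError(f"parameter must be one of {_PARAMETERS}, got {parameter!r}")
    rows = []
    for v in values:
        gp_v, cp_v = gp, cp
        if parameter in ("alpha", "beta"):
            gp_v = GompertzParams(**{**{"alpha": gp.alpha, "beta": gp.beta}, parameter: float(v)})
        else:
            cp_v = _dc_replace(cp, **{parameter: float(v)})
        rows.append((float(v), _evaluate_quantity(
            quantity, gp_v, cp_v, domain, density_method, extremum_variant, bracket)))
    return pd.DataFrame(rows, columns=[parameter, quantity])
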