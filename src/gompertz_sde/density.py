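"""Normalized stationary densities on a truncation domain.

The closed-form stationary solutions grow like ``exp(+b x^2 / 4D)`` far to the
right of the physical range and are therefore only normalizable on a finite
window; the quadrature solutions decay like ``exp(-b (ln x)^2 / 2D)`` and can
be normalized on arbitrarily wide windows.  Either way the constant is fixed
by numerical quadrature over the chosen domain, so every
:class:`NormalizedDensity` integrates to one on its own domain.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import CubicSpline, PchipInterpolator
from scipy.optimize import brentq

from ._closedform import _GRID_KNEE, support_grid

__all__ = ["NormalizedDensity", "DivergenceError"]

_MAX_LOG_SPREAD = 700.0  # exp() overflow guard after peak-shifting


def _integrate(f, lo: float, hi: float, peak: float) -> float:
    """Adaptive quadrature, split per decade beyond the linear/geometric knee.

    Wide supports span many decades; splitting keeps each adaptive panel
    well-scaled so no mass is silently skipped.
    """
    edges = [lo]
    if hi > _GRID_KNEE:
        e = _GRID_KNEE
        while e < hi:
            edges.append(e)
            e *= 10.0
    edges.append(hi)
    total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        val, _ = quad(f, a, b, points=[peak] if a < peak < b else None, limit=200)
        total += val
    return total


class DivergenceError(ArithmeticError):
    """The unnormalized density is non-finite or non-normalizable on the domain."""


@dataclass
class NormalizedDensity:
    """A stationary probability density normalized over ``domain``.

    Attributes
    ----------
    log_unnorm:
        Vectorized callable returning the unnormalized log-density.
    log_norm:
        ``log Integral exp(log_unnorm)`` over the domain; ``evaluate`` is
        ``exp(log_unnorm(x) - log_norm)``.
    norm_const:
        The multiplicative constant N with ``Pst = N * exp(log_unnorm)``
        (may underflow to 0.0 for extreme parameter sets; ``-log_norm`` is
        the robust representation).
    method:
        "closed_form" or "quadrature".
    params:
        Provenance of the generating parameter set.
    """

    log_unnorm: Callable[[np.ndarray], np.ndarray]
    domain: tuple[float, float]
    method: str
    params: dict = field(default_factory=dict)
    grid_n: int = 2001
    log_norm: float = field(init=False)
    norm_const: float = field(init=False)
    _grid: np.ndarray = field(init=False, repr=False)
    _cdf: PchipInterpolator = field(init=False, repr=False)
    _dlog: PchipInterpolator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not (math.isfinite(lo) and math.isfinite(hi) and 0 <= lo < hi):
            raise ValueError("domain must be a finite interval [lo, hi] with 0 <= lo < hi")
        grid = support_grid(lo, hi, self.grid_n)
        lu = np.asarray(self.log_unnorm(grid), dtype=float)
        if not np.all(np.isfinite(lu)):
            bad = grid[~np.isfinite(lu)]
            raise DivergenceError(
                "unnormalized log-density is non-finite on the domain "
                f"(first offending x = {bad[0]:.6g}); the closed form diverges outside "
                "its validity window - truncate the domain or use method='quadrature'"
            )
        shift = float(np.max(lu))
        # A log-density topping out at the right edge with an astronomical
        # spread is the closed form's divergent tail, not a peak; values far
        # below an interior peak merely underflow to zero density.
        if (shift - float(np.min(lu)) > _MAX_LOG_SPREAD
                and int(np.argmax(lu)) == lu.size - 1):
            raise DivergenceError(
                "log-density grows without bound toward the right edge of the "
                f"domain (spread {shift - float(np.min(lu)):.3g} in log units): "
                "the closed form is evaluated beyond its validity window - "
                "truncate the domain or use method='quadrature'"
            )
        peak = float(grid[int(np.argmax(lu))])
        Z = _integrate(lambda t: math.exp(float(self.log_unnorm(t)) - shift),
                       lo, hi, peak)
        if not (Z > 0 and math.isfinite(Z)):
            raise DivergenceError("density failed to normalize on the domain")
        self.log_norm = shift + math.log(Z)
        self.norm_const = math.exp(-self.log_norm) if -self.log_norm < 700 else 0.0
        self._grid = grid
        pdf_grid = np.exp(lu - self.log_norm)
        pdf_interp = PchipInterpolator(grid, pdf_grid, extrapolate=False)
        cdf = pdf_interp.antiderivative()
        self._cdf = cdf
        # mode refinement needs a smooth (non-shape-limited) derivative:
        # PCHIP flattens slopes at data extrema, exactly where the root lives
        self._dlog = CubicSpline(grid, lu, extrapolate=False).derivative()

    # -- evaluation ---------------------------------------------------------
    def evaluate(self, x):
        """Density value(s); zero outside the domain."""
        x = np.asarray(x, dtype=float)
        lo, hi = self.domain
        inside = (x >= lo) & (x <= hi)
        out = np.zeros_like(x, dtype=float)
        if np.any(inside):
            vals = np.exp(np.asarray(self.log_unnorm(np.where(inside, x, lo))) - self.log_norm)
            out = np.where(inside, vals, 0.0)
        return float(out) if out.ndim == 0 else out

    __call__ = evaluate

    def cdf(self, x):
        """Cumulative distribution on the domain (0 below, 1 above)."""
        x = np.asarray(x, dtype=float)
        lo, hi = self.domain
        xc = np.clip(x, lo, hi)
        total = float(self._cdf(hi))
        out = np.asarray(self._cdf(xc), dtype=float) / total
        return float(out) if out.ndim == 0 else out

    def mode(self) -> float:
        """Location of the global maximum, refined on the smooth log-density."""
        lu = self.log_unnorm(self._grid)
        i = int(np.argmax(lu))
        if i in (0, len(self._grid) - 1):
            return float(self._grid[i])
        a, b = self._grid[i - 1], self._grid[i + 1]
        da, db = float(self._dlog(a)), float(self._dlog(b))
        if da > 0 and db < 0:
            return float(brentq(self._dlog, a, b, xtol=1e-12))
        return float(self._grid[i])

    def integral(self) -> float:
        """Independent check of the normalization (should be 1)."""
        lo, hi = self.domain
        return _integrate(lambda t: float(self.evaluate(t)), lo, hi, self.mode())

    # -- export -------------------------------------------------------------
    def to_csv(self, path, grid=None) -> None:
        x = self._grid if grid is None else np.asarray(grid, dtype=float)
        p = self.evaluate(x)
        with open(path, "w") as fh:
            fh.write("x,pst\n")
            for xi, pi in zip(x, np.atleast_1d(p)):
                fh.write(f"{xi:.17g},{pi:.17g}\n")

    def metadata(self) -> dict:
        return {
            "params": self.params,
            "method": self.method,
            "domain": list(self.domain),
            "norm_const": self.norm_const,
            "log_norm": self.log_norm,
            "normalized_over_truncation_domain": True,
        }

    def write_metadata(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata(), fh, indent=2)

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_callable(cls, pdf, domain, method="quadrature", params=None, grid_n=2001):
        """Build from an (unnormalized) nonnegative pdf callable; test helper."""

        def log_unnorm(x):
            vals = np.asarray(pdf(np.asarray(x, dtype=float)), dtype=float)
            # floor far-tail underflow so the log stays finite
            return np.log(np.maximum(vals, 1e-300))

        return cls(log_unnorm=log_unnorm, domain=tuple(domain), method=method,
                   params=dict(params or {}), grid_n=grid_n)
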