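"""Deterministic improved Gompertz growth model.

The model is the growth law

    dx/dt = alpha*x - beta*x*ln(x),   alpha, beta > 0,

for a tumor-cell number ``x > 0``.  It has a single attracting fixed point
``xs = exp(alpha/beta)`` and derives from the potential

    V(x) = -((2*alpha + beta)/4) * x**2 + (beta/2) * x**2 * ln(x),

in the standard gradient sense ``F(x) = -V'(x)``.  The ODE is solved in
closed form: ``ln x(t) = alpha/beta + (ln x0 - alpha/beta) * exp(-beta*t)``,
so every trajectory approaches ``xs`` monotonically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GompertzParams",
    "Trajectory",
    "deterministic_drift",
    "potential",
    "stable_state",
    "solve_deterministic",
    "relaxation_time",
]


@dataclass(frozen=True)
class GompertzParams:
    """Birth rate ``alpha`` and death rate ``beta`` (both > 0, per unit time)."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    @property
    def stable_state(self) -> float:
        return math.exp(self.alpha / self.beta)


@dataclass(frozen=True)
class Trajectory:
    """A deterministic solution sampled on a time grid."""

    times: np.ndarray
    values: np.ndarray
    params: GompertzParams
    x0: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("times must be a non-empty 1-d grid")
        if t.size != x.size:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(x <= 0):
            raise ValueError("values must be strictly positive")
        if t[0] == 0.0 and not math.isclose(x[0], self.x0, rel_tol=1e-12, abs_tol=1e-12):
            raise ValueError("first value must equal x0 when the grid starts at t = 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", x)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("t,x\n")
            for t, x in zip(self.times, self.values):
                fh.write(f"{t:.17g},{x:.17g}\n")

    def metadata(self) -> dict:
        return {
            "alpha": self.params.alpha,
            "beta": self.params.beta,
            "x0": self.x0,
            "n_points": int(self.times.size),
            "t_final": float(self.times[-1]),
        }

    def write_metadata(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata(), fh, indent=2)


def deterministic_drift(x, gp: GompertzParams):
    """Growth rate ``alpha*x - beta*x*ln(x)``.

    ``x`` must be strictly positive (scalar or array).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("deterministic drift requires x > 0 (ln undefined)")
    out = gp.alpha * x - gp.beta * x * np.log(x)
    return float(out) if out.ndim == 0 else out


def potential(x, gp: GompertzParams):
    """Potential ``V(x) = -((2a+b)/4) x^2 + (b/2) x^2 ln x`` with V(0) = 0.

    The growth law is the gradient flow ``dx/dt = -V'(x)``; the limit value 0
    is returned at x = 0 so plotting grids may include the origin.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("potential requires x >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        xlx2 = np.where(x > 0, x * x * np.log(np.where(x > 0, x, 1.0)), 0.0)
    out = -((2 * gp.alpha + gp.beta) / 4.0) * x * x + (gp.beta / 2.0) * xlx2
    return float(out) if out.ndim == 0 else out


def stable_state(gp: GompertzParams) -> float:
    """The attracting fixed point ``exp(alpha/beta)`` of the growth law."""
    return gp.stable_state


def _log_solution(gp: GompertzParams, x0: float, t):
    r = gp.alpha / gp.beta
    return r + (math.log(x0) - r) * np.exp(-gp.beta * np.asarray(t, dtype=float))


def solve_deterministic(gp: GompertzParams, x0: float, times) -> Trajectory:
    """Closed-form trajectory on a sorted, nonnegative time grid."""
    if x0 <= 0:
        raise ValueError("x0 must be > 0")
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    x = np.exp(_log_solution(gp, x0, t))
    return Trajectory(times=t, values=x, params=gp, x0=float(x0))


def relaxation_time(gp: GompertzParams, x0: float, rel_tol: float) -> float:
    """Smallest t with ``|x(t) - xs| <= rel_tol * xs``, from the closed form.

    The approach to ``xs`` is monotone, so the hitting time of the tolerance
    band is unique and solvable analytically:  with c = alpha/beta - ln(x0),
    ``ln x(t) - ln xs = -c * exp(-beta*t)`` and the band edge corresponds to
    ``exp(-beta*t) = delta / |c|`` where delta is ``-ln(1 - rel_tol)`` from
    below and ``ln(1 + rel_tol)`` from above.
    """
    if not 0 < rel_tol < 1:
        raise ValueError("rel_tol must lie in (0, 1)")
    if x0 <= 0:
        raise ValueError("x0 must be > 0")
    c = gp.alpha / gp.beta - math.log(x0)  # > 0 iff x0 < xs
    if c == 0.0:
        return 0.0
    delta = -math.log1p(-rel_tol) if c > 0 else math.log1p(rel_tol)
    if abs(c) <= delta:
        return 0.0
    return math.log(abs(c) / delta) / gp.beta
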