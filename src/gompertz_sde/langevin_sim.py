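"""Langevin simulation of the colored-noise growth model.

The simulated system is the pair

    dx/dt  = alpha*x - beta*x*ln x + x*xi(t) + eta(t),
    dxi/dt = -xi/tau + varsigma(t)/tau,

where eta is additive white noise (intensity Q), varsigma is the white noise
driving the Ornstein-Uhlenbeck process xi (intensity D2) and the two white
noises are cross-correlated with coefficient lambda2.  Per time step the two
Gaussian increments are built from one pair of standard normals,

    U = sqrt(2*D2*dt) * w,    V = sqrt(2*Q*dt) * (lam*w + sqrt(1-lam^2)*z),

so that corr(U, V) = lam.

Three integration schemes are provided:

``printed_rk4``
    An archival transcription of a published stochastic Runge-Kutta step in
    which the multiplicative-scale increment U is added to the x update and
    V/tau to the xi update (and one fourth-stage argument reuses dt*h3 where
    the pattern implies dt*k3).  Kept verbatim for comparison; its stationary
    statistics do not converge to the model's.
``corrected``
    Classical RK4 on the coupled drift plus the increments in the roles the
    construction above assigns: V (additive, sqrt(2*Q*dt) scale) drives x and
    U/tau drives the Ornstein-Uhlenbeck update.  This is the quantitative
    two-dimensional reference.
``ucna_reference``
    Euler-Maruyama for the reduced one-dimensional Ito diffusion
    dx = G(x) dt + sqrt(2*H(x)) dW, whose stationary density is exactly the
    analytic colored-noise density - the simulation oracle for it.

Reproducibility: each path owns an independent generator seeded by
(master seed, path index), so ensembles do not depend on chunking or
execution order.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model_core import GompertzParams
from .spd_colored import ColoredNoiseParams, diffusion_H, drift_G

__all__ = [
    "SimConfig",
    "NoiseIncrements",
    "Ensemble",
    "HistogramDensity",
    "FirstPassageResult",
    "noise_drift",
    "draw_increments",
    "step_printed_rk4",
    "step_corrected",
    "step_ucna_reference",
    "simulate",
    "empirical_density",
    "first_passage_sample",
]

_SCHEMES = ("printed_rk4", "corrected", "ucna_reference")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulation run.

    burn_in (steps discarded before stationary sampling) defaults to half of
    n_steps.  ``thin`` controls the recording stride (state stored every
    ``thin`` steps); ``floor`` is the positivity floor applied to x because
    ln x is evaluated at every stage.
    """

    dt: float
    n_steps: int
    n_paths: int = 1
    burn_in: Optional[int] = None
    seed: int = 0
    x0: float = 1.0
    xi0: float = 0.0
    scheme: str = "corrected"
    floor: float = 1e-8
    thin: int = 1
    record_xi: bool = False

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.n_steps < 1 or self.n_paths < 1 or self.thin < 1:
            raise ValueError("n_steps, n_paths and thin must be >= 1")
        if self.x0 <= 0:
            raise ValueError("x0 must be > 0")
        if not self.floor > 0:
            raise ValueError("floor must be > 0")
        if self.scheme not in _SCHEMES:
            raise ValueError(f"scheme must be one of {_SCHEMES}")
        if self.burn_in is None:
            object.__setattr__(self, "burn_in", self.n_steps // 2)
        if not 0 <= self.burn_in < self.n_steps:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_steps")


@dataclass(frozen=True)
class NoiseIncrements:
    """Paired Gaussian increments: var(U) = 2*D*dt, var(V) = 2*Q*dt, corr = lam."""

    U: np.ndarray
    V: np.ndarray


def draw_increments(n: int, dt: float, D: float, Q: float, lam: float,
                    rng: np.random.Generator) -> NoiseIncrements:
    """Draw ``n`` correlated increment pairs from a single RNG stream."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if abs(lam) > 1:
        raise ValueError("|lam| must be <= 1")
    if D < 0 or Q < 0:
        raise ValueError("intensities must be >= 0")
    w = rng.standard_normal(n)
    z = rng.standard_normal(n)
    U = math.sqrt(2.0 * D * dt) * w
    V = math.sqrt(2.0 * Q * dt) * (lam * w + math.sqrt(1.0 - lam * lam) * z)
    return NoiseIncrements(U=U, V=V)


def noise_drift(x, xi, gp: GompertzParams, floor: float = 1e-8):
    """Instantaneous growth rate alpha*x - beta*x*ln x + x*xi (x floored)."""
    x = np.maximum(np.asarray(x, dtype=float), floor)
    return gp.alpha * x - gp.beta * x * np.log(x) + x * np.asarray(xi, dtype=float)


def step_printed_rk4(x, xi, gp: GompertzParams, cp: ColoredNoiseParams,
                     dt: float, U, V, floor: float = 1e-8):
    """One step of the stochastic Runge-Kutta scheme exactly as printed.

    U (the sqrt(2*D2*dt)-scale increment) is added to the x update and V/tau
    to the xi update; V enters the x stages and U the xi stages; the fourth
    x-stage reuses dt*h3 in its xi argument.  Archival fidelity only.
    """
    if cp.tau == 0:
        raise ValueError("printed scheme divides by tau; tau must be > 0")
    tau = cp.tau
    x = np.asarray(x, dtype=float)
    xi = np.asarray(xi, dtype=float)
    f = lambda y, z: noise_drift(y, z, gp, floor)
    k1 = -xi / tau
    h1 = f(x, xi)
    k2 = -(xi + 0.5 * dt * k1 + U) / tau
    h2 = f(x + 0.5 * dt * h1 + V, xi + 0.5 * dt * k1 + U)
    k3 = -(xi + 0.5 * dt * k2 + U) / tau
    h3 = f(x + 0.5 * dt * h2 + V, xi + 0.5 * dt * k2 + U)
    k4 = -(xi + dt * k3 + U) / tau
    h4 = f(x + dt * h3 + V, xi + dt * h3 + U)  # dt*h3 as printed
    x_next = x + dt / 6.0 * (h1 + 2 * h2 + 2 * h3 + h4) + U
    xi_next = xi + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4) + V / tau
    return np.maximum(x_next, floor), xi_next


def step_corrected(x, xi, gp: GompertzParams, cp: ColoredNoiseParams,
                   dt: float, U, V, floor: float = 1e-8):
    """Classical RK4 drift step plus increments in their consistent roles.

    x receives the additive increment V and xi receives U/tau, so the
    Ornstein-Uhlenbeck marginal has variance D2/tau and autocovariance
    (D2/tau) exp(-|t-s|/tau) in the stationary state.
    """
    if cp.tau == 0:
        raise ValueError("the two-dimensional scheme divides by tau; tau must be > 0")
    tau = cp.tau
    x = np.asarray(x, dtype=float)
    xi = np.asarray(xi, dtype=float)
    f = lambda y, z: noise_drift(y, z, gp, floor)
    k1 = -xi / tau
    h1 = f(x, xi)
    k2 = -(xi + 0.5 * dt * k1) / tau
    h2 = f(x + 0.5 * dt * h1, xi + 0.5 * dt * k1)
    k3 = -(xi + 0.5 * dt * k2) / tau
    h3 = f(x + 0.5 * dt * h2, xi + 0.5 * dt * k2)
    k4 = -(xi + dt * k3) / tau
    h4 = f(x + dt * h3, xi + dt * k3)
    x_next = x + dt / 6.0 * (h1 + 2 * h2 + 2 * h3 + h4) + V
    xi_next = xi + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4) + U / tau
    return np.maximum(x_next, floor), xi_next


def _ucna_step(x, gp, cp, dt, w, floor):
    x = np.asarray(x, dtype=float)
    drift = drift_G(x, gp, cp)
    amp = np.sqrt(2.0 * diffusion_H(x, gp, cp) * dt)
    return np.maximum(x + drift * dt + amp * np.asarray(w, dtype=float), floor)


def step_ucna_reference(x, gp: GompertzParams, cp: ColoredNoiseParams,
                        dt: float, rng: np.random.Generator, floor: float = 1e-8):
    """Euler-Maruyama step of the reduced diffusion dx = G dt + sqrt(2H) dW."""
    w = rng.standard_normal(np.shape(np.asarray(x)))
    return _ucna_step(x, gp, cp, dt, w, floor)


@dataclass
class Ensemble:
    """Recorded trajectories with full provenance."""

    times: np.ndarray
    values: np.ndarray  # (n_paths, n_recorded)
    config: SimConfig
    gp: GompertzParams
    cp: ColoredNoiseParams
    xi: Optional[np.ndarray] = None
    clip_count: int = 0

    def stationary_samples(self) -> np.ndarray:
        """Flattened x samples recorded after the burn-in period."""
        keep = self.times > self.config.burn_in * self.config.dt
        return self.values[:, keep].ravel()

    def trajectory_to_csv(self, path, path_index: int = 0) -> None:
        cols = "t,x,xi\n" if self.xi is not None else "t,x\n"
        with open(path, "w") as fh:
            fh.write(cols)
            for j, t in enumerate(self.times):
                row = f"{t:.17g},{self.values[path_index, j]:.17g}"
                if self.xi is not None:
                    row += f",{self.xi[path_index, j]:.17g}"
                fh.write(row + "\n")

    def metadata(self) -> dict:
        return {
            "alpha": self.gp.alpha, "beta": self.gp.beta,
            "D2": self.cp.D2, "Q": self.cp.Q,
            "lambda2": self.cp.lambda2, "tau": self.cp.tau,
            "seed": self.config.seed, "scheme": self.config.scheme,
            "dt": self.config.dt, "n_steps": self.config.n_steps,
            "n_paths": self.config.n_paths, "burn_in": self.config.burn_in,
            "thin": self.config.thin, "clip_count": int(self.clip_count),
        }

    def write_metadata(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata(), fh, indent=2)


def _path_rngs(seed: int, n_paths: int) -> list:
    return [np.random.default_rng([seed, i]) for i in range(n_paths)]


def simulate(gp: GompertzParams, cp: ColoredNoiseParams, config: SimConfig) -> Ensemble:
    """Run the configured scheme for n_paths x n_steps and record the states."""
    n_paths, n_steps, dt = config.n_paths, config.n_steps, config.dt
    rngs = _path_rngs(config.seed, n_paths)
    two_dim = config.scheme in ("printed_rk4", "corrected")
    x = np.full(n_paths, config.x0, dtype=float)
    xi = np.full(n_paths, config.xi0, dtype=float)

    rec_idx = np.arange(0, n_steps + 1, config.thin)
    times = rec_idx * dt
    values = np.empty((n_paths, rec_idx.size))
    xis = np.empty_like(values) if (two_dim and config.record_xi) else None
    values[:, 0] = x
    if xis is not None:
        xis[:, 0] = xi

    step_fn = {"printed_rk4": step_printed_rk4, "corrected": step_corrected}.get(config.scheme)
    clip_count = 0
    rec_pos = 1
    chunk = 4096
    for start in range(0, n_steps, chunk):
        m = min(chunk, n_steps - start)
        if two_dim:
            z = np.stack([g.standard_normal((m, 2)) for g in rngs])  # (paths, m, 2)
            U = math.sqrt(2.0 * cp.D2 * dt) * z[:, :, 0]
            V = math.sqrt(2.0 * cp.Q * dt) * (
                cp.lambda2 * z[:, :, 0]
                + math.sqrt(1.0 - cp.lambda2 ** 2) * z[:, :, 1]
            )
        else:
            w = np.stack([g.standard_normal(m) for g in rngs])
        for j in range(m):
            if two_dim:
                x_new, xi = step_fn(x, xi, gp, cp, dt, U[:, j], V[:, j], floor=config.floor)
            else:
                x_new = _ucna_step(x, gp, cp, dt, w[:, j], config.floor)
            clip_count += int(np.count_nonzero(x_new <= config.floor))
            x = x_new
            i = start + j + 1
            if i % config.thin == 0:
                values[:, rec_pos] = x
                if xis is not None:
                    xis[:, rec_pos] = xi
                rec_pos += 1

    total = n_paths * n_steps
    if clip_count > 0.01 * total:
        warnings.warn(
            f"positivity floor hit on {clip_count}/{total} steps (> 1%); "
            "the time step dt is likely too large for these noise intensities",
            RuntimeWarning,
        )
    return Ensemble(times=times, values=values, config=config, gp=gp, cp=cp,
                    xi=xis, clip_count=clip_count)


@dataclass(frozen=True)
class HistogramDensity:
    """Bin-count density normalized to unit integral over its domain."""

    edges: np.ndarray
    density: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[1:] + self.edges[:-1])

    def integral(self) -> float:
        return float(np.sum(self.density * np.diff(self.edges)))


def empirical_density(samples, bins: int = 60, domain=None) -> HistogramDensity:
    """Histogram density of stationary samples (integrates to 1 by construction)."""
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("no samples provided")
    rng_ = None if domain is None else tuple(domain)
    density, edges = np.histogram(samples, bins=bins, range=rng_, density=True)
    return HistogramDensity(edges=edges, density=density)


@dataclass(frozen=True)
class FirstPassageResult:
    """Upward first-passage times; censored paths are reported separately."""

    times: np.ndarray
    n_censored: int
    horizon: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.times))

    @property
    def std_error(self) -> float:
        return float(np.std(self.times, ddof=1) / math.sqrt(self.times.size))


def first_passage_sample(gp: GompertzParams, cp: ColoredNoiseParams, config: SimConfig,
                         x_start: float, x_target: float) -> FirstPassageResult:
    """Per path, the first time x reaches ``x_target`` starting at ``x_start``.

    Passage times are linearly interpolated within the crossing step.  Paths
    not arriving within n_steps*dt are censored; if every path is censored a
    RuntimeError advises a longer horizon.
    """
    if x_start > x_target:
        raise ValueError("upward passage requires x_start <= x_target")
    n_paths, n_steps, dt = config.n_paths, config.n_steps, config.dt
    if x_start == x_target:
        return FirstPassageResult(times=np.zeros(n_paths), n_censored=0,
                                  horizon=n_steps * dt)
    rngs = _path_rngs(config.seed, n_paths)
    two_dim = config.scheme in ("printed_rk4", "corrected")
    step_fn = {"printed_rk4": step_printed_rk4, "corrected": step_corrected}.get(config.scheme)

    x = np.full(n_paths, float(x_start))
    xi = np.full(n_paths, config.xi0, dtype=float)
    t_hit = np.full(n_paths, np.nan)
    active = np.ones(n_paths, dtype=bool)
    chunk = 2048
    for start in range(0, n_steps, chunk):
        m = min(chunk, n_steps - start)
        if two_dim:
            z = np.stack([g.standard_normal((m, 2)) for g in rngs])
            U = math.sqrt(2.0 * cp.D2 * dt) * z[:, :, 0]
            V = math.sqrt(2.0 * cp.Q * dt) * (
                cp.lambda2 * z[:, :, 0]
                + math.sqrt(1.0 - cp.lambda2 ** 2) * z[:, :, 1]
            )
        else:
            w = np.stack([g.standard_normal(m) for g in rngs])
        for j in range(m):
            x_prev = x.copy()
            if two_dim:
                x, xi = step_fn(x, xi, gp, cp, dt, U[:, j], V[:, j], floor=config.floor)
            else:
                x = _ucna_step(x, gp, cp, dt, w[:, j], config.floor)
            crossed = active & (x >= x_target)
            if np.any(crossed):
                frac = (x_target - x_prev[crossed]) / (x[crossed] - x_prev[crossed])
                frac = np.clip(frac, 0.0, 1.0)
                t_hit[crossed] = (start + j + frac) * dt
                active[crossed] = False
            if not np.any(active):
                break
        if not np.any(active):
            break

    times = t_hit[~np.isnan(t_hit)]
    n_censored = int(np.count_nonzero(np.isnan(t_hit)))
    if times.size == 0:
        raise RuntimeError(
            "all paths were censored before reaching x_target; "
            "increase n_steps (longer horizon) or reconsider the target"
        )
    return FirstPassageResult(times=times, n_censored=n_censored, horizon=n_steps * dt)
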