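"""Caption-sourced parameter sets and curve builders for figure reproduction.

The published figures are the only "data" the model has; each entry below
hard-codes the caption's parameter set and produces the corresponding curves
as tidy DataFrames (one per panel/curve family).  Plotting is deliberately
left to the caller - the curves are the reproducible artifact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .langevin_sim import SimConfig, simulate
from .model_core import GompertzParams, potential, solve_deterministic
from .spd_colored import ColoredNoiseParams, modified_potential_colored, spd_colored
from .spd_white import WhiteNoiseParams, modified_potential_white, spd_white
from .transient_stats import sweep

__all__ = ["FIGURES", "reproduce_figure", "figure_settings"]

_X = np.linspace(0.0, 6.0, 601)
_XWIDE = np.linspace(0.0, 10.0, 501)
_DOMAIN = (0.0, 10.0)


def _potential_curves(panels):
    frames = []
    for label, gp in panels:
        frames.append(pd.DataFrame({"panel": label, "x": _X, "V": potential(_X, gp)}))
    return {"potential": pd.concat(frames, ignore_index=True)}


def _phi1_curves(panels, wp):
    frames = []
    for label, gp in panels:
        frames.append(pd.DataFrame({
            "panel": label, "x": _X[_X > 0],
            "phi1": modified_potential_white(_X[_X > 0], gp, wp)}))
    return {"phi1": pd.concat(frames, ignore_index=True)}


def _phi2_curves(panels, cp):
    frames = []
    for label, gp in panels:
        frames.append(pd.DataFrame({
            "panel": label, "x": _X[_X > 0],
            "phi2": modified_potential_colored(_X[_X > 0], gp, cp)}))
    return {"phi2": pd.concat(frames, ignore_index=True)}


def _spd_family(model, base_gp, base_noise, vary, values, method="closed_form"):
    """SPD curves varying one parameter of either the model or the noise."""
    frames = []
    for v in values:
        gp, noise = base_gp, base_noise
        if vary in ("alpha", "beta"):
            gp = GompertzParams(**{"alpha": base_gp.alpha, "beta": base_gp.beta, vary: v})
        else:
            kw = {f.name: getattr(base_noise, f.name) for f in base_noise.__dataclass_fields__.values()}
            kw[vary] = v
            noise = type(base_noise)(**kw)
        dens = (spd_white if model == "white" else spd_colored)(
            gp, noise, method=method, domain=_DOMAIN)
        frames.append(pd.DataFrame({vary: v, "x": _XWIDE, "pst": dens.evaluate(_XWIDE)}))
    return {"spd": pd.concat(frames, ignore_index=True)}


def _xm_sweep(panel_param, panel_values, fixed_cp, alpha=0.15,
              betas=np.arange(0.2, 1.01, 0.05), variant="printed"):
    frames = []
    for v in panel_values:
        kw = {f.name: getattr(fixed_cp, f.name) for f in fixed_cp.__dataclass_fields__.values()}
        kw[panel_param] = v
        cp = ColoredNoiseParams(**kw)
        rows = []
        for b in betas:
            gp = GompertzParams(alpha, float(b))
            tab = sweep("xm", "beta", [float(b)], gp, cp, extremum_variant=variant)
            rows.append((float(b), float(tab["xm"].iloc[0])))
        df = pd.DataFrame(rows, columns=["beta", "xm"])
        df.insert(0, panel_param, v)
        frames.append(df)
    return {"xm": pd.concat(frames, ignore_index=True)}


def _trajectory(gp, cp=None, seed=0, scheme=None, t_final=60.0, dt=0.01):
    if scheme is None:
        times = np.arange(0.0, t_final + dt, dt)
        traj = solve_deterministic(gp, 1.0, times)
        return {"trajectory": pd.DataFrame({"t": traj.times, "x": traj.values})}
    n = int(round(t_final / dt))
    cfg = SimConfig(dt=dt, n_steps=n, n_paths=1, seed=seed, scheme=scheme, thin=5)
    ens = simulate(gp, cp, cfg)
    return {"trajectory": pd.DataFrame({"t": ens.times, "x": ens.values[0]})}


def _spd_with_simulation(model, sets, noise, seed=0):
    """Analytic SPD (solid line) plus a simulated stationary histogram (markers)."""
    frames, hist_frames = [], []
    for label, gp in sets:
        if model == "white":
            dens = spd_white(gp, noise, method="closed_form", domain=_DOMAIN)
            cp = ColoredNoiseParams(D2=noise.D1, Q=noise.Q, lambda2=noise.lambda1, tau=1e-6)
        else:
            dens = spd_colored(gp, noise, method="closed_form", domain=_DOMAIN)
            cp = noise
        frames.append(pd.DataFrame({"panel": label, "x": _XWIDE,
                                    "pst": dens.evaluate(_XWIDE)}))
        cfg = SimConfig(dt=0.01, n_steps=40_000, n_paths=64, seed=seed,
                        scheme="ucna_reference", thin=50)
        ens = simulate(gp, cp, cfg)
        samples = ens.stationary_samples()
        counts, edges = np.histogram(samples, bins=40, range=_DOMAIN, density=True)
        hist_frames.append(pd.DataFrame({
            "panel": label, "x": 0.5 * (edges[1:] + edges[:-1]), "pst_sim": counts}))
    return {"spd": pd.concat(frames, ignore_index=True),
            "spd_sim": pd.concat(hist_frames, ignore_index=True)}


def _stat_sweep(quantity, parameter, values, panel_param, panel_values, gp, cp):
    frames = []
    for pv in panel_values:
        gp_v, cp_v = gp, cp
        if panel_param in ("alpha", "beta"):
            gp_v = GompertzParams(**{"alpha": gp.alpha, "beta": gp.beta, panel_param: pv})
        else:
            kw = {f.name: getattr(cp, f.name) for f in cp.__dataclass_fields__.values()}
            kw[panel_param] = pv
            cp_v = ColoredNoiseParams(**kw)
        df = sweep(quantity, parameter, values, gp_v, cp_v)
        df.insert(0, panel_param, pv)
        frames.append(df)
    return {quantity: pd.concat(frames, ignore_index=True)}


_D2_GRID = [round(v, 2) for v in np.arange(0.2, 0.61, 0.05)]
_Q_GRID = [round(v, 2) for v in np.arange(0.10, 0.31, 0.02)]
_D2_MOMENT_GRID = [round(v, 2) for v in np.arange(0.05, 1.01, 0.05)]

FIGURES = {
    "fig1": dict(
        settings="deterministic potential V(x); (a) alpha=0.25, beta=0.2; (b) alpha=0.2, beta=0.25",
        build=lambda seed: _potential_curves(
            [("a", GompertzParams(0.25, 0.2)), ("b", GompertzParams(0.2, 0.25))]),
    ),
    "fig2": dict(
        settings="modified potential Phi1; D1=0.25, Q=0.15, lambda1=0.1; "
                 "(a) alpha=0.25, beta=0.2; (b) alpha=0.2, beta=0.25",
        build=lambda seed: _phi1_curves(
            [("a", GompertzParams(0.25, 0.2)), ("b", GompertzParams(0.2, 0.25))],
            WhiteNoiseParams(0.25, 0.15, 0.1)),
    ),
    "fig3": dict(
        settings="white-noise SPD for alpha in {0.25, 0.35, 0.45}; "
                 "beta=0.1, D1=0.25, Q=0.15, lambda1=0.2",
        build=lambda seed: _spd_family("white", GompertzParams(0.25, 0.1),
                                       WhiteNoiseParams(0.25, 0.15, 0.2),
                                       "alpha", [0.25, 0.35, 0.45]),
    ),
    "fig4": dict(
        settings="white-noise SPD for beta in {0.1, 0.15, 0.2}; "
                 "alpha=0.3, D1=0.25, Q=0.15, lambda1=0.2",
        build=lambda seed: _spd_family("white", GompertzParams(0.3, 0.1),
                                       WhiteNoiseParams(0.25, 0.15, 0.2),
                                       "beta", [0.1, 0.15, 0.2]),
    ),
    "fig5": dict(
        settings="white-noise SPD for D1 in {0.15, 0.25, 0.35}; "
                 "alpha=0.3, beta=0.1, Q=0.15, lambda1=0.2",
        build=lambda seed: _spd_family("white", GompertzParams(0.3, 0.1),
                                       WhiteNoiseParams(0.25, 0.15, 0.2),
                                       "D1", [0.15, 0.25, 0.35]),
    ),
    "fig6": dict(
        settings="white-noise SPD for Q in {0.10, 0.15, 0.20}; "
                 "alpha=0.3, beta=0.1, D1=0.25, lambda1=0.2",
        build=lambda seed: _spd_family("white", GompertzParams(0.3, 0.1),
                                       WhiteNoiseParams(0.25, 0.15, 0.2),
                                       "Q", [0.10, 0.15, 0.20]),
    ),
    "fig7": dict(
        settings="modified potential Phi2; D2=0.35, Q=0.15, lambda2=0.1, tau=0.2; "
                 "(a) alpha=0.25, beta=0.2; (b) alpha=0.2, beta=0.25",
        build=lambda seed: _phi2_curves(
            [("a", GompertzParams(0.25, 0.2)), ("b", GompertzParams(0.2, 0.25))],
            ColoredNoiseParams(0.35, 0.15, 0.1, 0.2)),
    ),
    "fig8": dict(
        settings="SPD extremum xm vs beta (alpha=0.15); (a) D2 in {0.2, 0.35, 0.5} at "
                 "Q=0.15, lambda2=0.1, tau=0.2; (b) Q in {0.10, 0.15, 0.20} at D2=0.35",
        build=lambda seed: {
            "xm_a": _xm_sweep("D2", [0.2, 0.35, 0.5],
                              ColoredNoiseParams(0.35, 0.15, 0.1, 0.2))["xm"],
            "xm_b": _xm_sweep("Q", [0.10, 0.15, 0.20],
                              ColoredNoiseParams(0.35, 0.15, 0.1, 0.2))["xm"],
        },
    ),
    "fig9": dict(
        settings="SPD extremum xm vs beta (alpha=0.15); (a) lambda2 in {0, 0.3, 0.6, 0.9} "
                 "at D2=0.35, Q=0.15, tau=0.2; (b) tau in {0.1, 0.2, 0.4} at lambda2=0.1",
        build=lambda seed: {
            "xm_a": _xm_sweep("lambda2", [0.0, 0.3, 0.6, 0.9],
                              ColoredNoiseParams(0.35, 0.15, 0.1, 0.2))["xm"],
            "xm_b": _xm_sweep("tau", [0.1, 0.2, 0.4],
                              ColoredNoiseParams(0.35, 0.15, 0.1, 0.2))["xm"],
        },
    ),
    "fig10": dict(
        settings="(a) deterministic trajectory alpha=0.25, beta=0.2, x0=1; "
                 "(b) white-noise trajectory D1=0.25, Q=0.15, lambda1=0.1",
        build=lambda seed: {
            "trajectory_a": _trajectory(GompertzParams(0.25, 0.2))["trajectory"],
            "trajectory_b": _trajectory(
                GompertzParams(0.25, 0.2),
                ColoredNoiseParams(D2=0.25, Q=0.15, lambda2=0.1, tau=1e-6),
                seed=seed, scheme="ucna_reference")["trajectory"],
        },
    ),
    "fig11": dict(
        settings="colored-noise trajectories; alpha=0.25, beta=0.2, D2=0.35, Q=0.15; "
                 "(a) tau=0.2; (b) lambda2=0.1",
        build=lambda seed: {
            "trajectory_a": _trajectory(
                GompertzParams(0.25, 0.2), ColoredNoiseParams(0.35, 0.15, 0.0, 0.2),
                seed=seed, scheme="corrected")["trajectory"],
            "trajectory_b": _trajectory(
                GompertzParams(0.25, 0.2), ColoredNoiseParams(0.35, 0.15, 0.1, 0.2),
                seed=seed, scheme="corrected")["trajectory"],
        },
    ),
    "fig12": dict(
        settings="white-noise SPD vs simulation; lambda1=0.2, D1=0.25, Q=0.15; "
                 "(a) alpha=0.25/0.45, beta=0.1; (b) alpha=0.3, beta=0.15/0.25",
        build=lambda seed: _spd_with_simulation(
            "white",
            [("a1", GompertzParams(0.25, 0.1)), ("a2", GompertzParams(0.45, 0.1)),
             ("b1", GompertzParams(0.3, 0.15)), ("b2", GompertzParams(0.3, 0.25))],
            WhiteNoiseParams(0.25, 0.15, 0.2), seed=seed),
    ),
    "fig13": dict(
        settings="colored-noise SPD vs simulation; lambda2=0.2, tau=0.1, D2=0.35, Q=0.15; "
                 "(a) alpha=0.25/0.45, beta=0.1; (b) alpha=0.3, beta=0.15/0.25",
        build=lambda seed: _spd_with_simulation(
            "colored",
            [("a1", GompertzParams(0.25, 0.1)), ("a2", GompertzParams(0.45, 0.1)),
             ("b1", GompertzParams(0.3, 0.15)), ("b2", GompertzParams(0.3, 0.25))],
            ColoredNoiseParams(0.35, 0.15, 0.2, 0.1), seed=seed),
    ),
    "fig14": dict(
        settings="colored SPD; D2=0.3, Q=0.15, lambda2=0.2, tau=0.1; "
                 "(a) beta=0.1, alpha in {0.25, 0.35, 0.45}; (b) alpha=0.3, beta in {0.1, 0.15, 0.2}",
        build=lambda seed: {
            "spd_a": _spd_family("colored", GompertzParams(0.25, 0.1),
                                 ColoredNoiseParams(0.3, 0.15, 0.2, 0.1),
                                 "alpha", [0.25, 0.35, 0.45])["spd"],
            "spd_b": _spd_family("colored", GompertzParams(0.3, 0.1),
                                 ColoredNoiseParams(0.3, 0.15, 0.2, 0.1),
                                 "beta", [0.1, 0.15, 0.2])["spd"],
        },
    ),
    "fig15": dict(
        settings="colored SPD; alpha=0.3, beta=0.1, lambda2=0.2, tau=0.1; "
                 "(a) D2 in {0.25, 0.35, 0.45} at Q=0.15; (b) Q in {0.10, 0.15, 0.20} at D2=0.35",
        build=lambda seed: {
            "spd_a": _spd_family("colored", GompertzParams(0.3, 0.1),
                                 ColoredNoiseParams(0.35, 0.15, 0.2, 0.1),
                                 "D2", [0.25, 0.35, 0.45])["spd"],
            "spd_b": _spd_family("colored", GompertzParams(0.3, 0.1),
                                 ColoredNoiseParams(0.35, 0.15, 0.2, 0.1),
                                 "Q", [0.10, 0.15, 0.20])["spd"],
        },
    ),
    "fig16": dict(
        settings="colored SPD; alpha=0.3, beta=0.1, D2=0.35, Q=0.15; "
                 "(a) lambda2 in {0, 0.3, 0.6, 0.9} at tau=0.1; (b) tau in {0.1, 0.2, 0.3} at lambda2=0.2",
        build=lambda seed: {
            "spd_a": _spd_family("colored", GompertzParams(0.3, 0.1),
                                 ColoredNoiseParams(0.35, 0.15, 0.0, 0.1),
                                 "lambda2", [0.0, 0.3, 0.6, 0.9])["spd"],
            "spd_b": _spd_family("colored", GompertzParams(0.3, 0.1),
                                 ColoredNoiseParams(0.35, 0.15, 0.2, 0.1),
                                 "tau", [0.1, 0.2, 0.3])["spd"],
        },
    ),
    "fig17": dict(
        settings="ln T (Kramers) vs D2; Q=0.15, lambda2=0.1, tau=0.2; "
                 "(a) beta=0.2, alpha in {0.25, 0.3, 0.35}; (b) alpha=0.3, beta in {0.15, 0.2, 0.25}",
        build=lambda seed: {
            "lnT_a": _stat_sweep("lnT_kramers", "D2", _D2_GRID, "alpha", [0.25, 0.3, 0.35],
                                 GompertzParams(0.25, 0.2),
                                 ColoredNoiseParams(0.35, 0.15, 0.1, 0.2))["lnT_kramers"],
            "lnT_b": _stat_sweep("lnT_kramers", "D2", _D2_GRID, "beta", [0.15, 0.25],
                                 GompertzParams(0.3, 0.2),
                                 ColoredNoiseParams(0.35, 0.15, 0.1, 0.2))["lnT_kramers"],
        },
    ),
    "fig18": dict(
        settings="ln T (Kramers) vs D2; Q=0.15, alpha=0.25, beta=0.2; "
                 "(a) lambda2 in {0, 0.3, 0.6} at tau=0.2; (b) tau in {0.1, 0.2, 0.4} at lambda2=0.1",
        build=lambda seed: {
            "lnT_a": _stat_sweep("lnT_kramers", "D2", _D2_GRID, "lambda2", [0.0, 0.3, 0.6],
                                 GompertzParams(0.25, 0.2),
                                 ColoredNoiseParams(0.35, 0.15, 0.1, 0.2))["lnT_kramers"],
            "lnT_b": _stat_sweep("lnT_kramers", "D2", _D2_GRID, "tau", [0.1, 0.2, 0.4],
                                 GompertzParams(0.25, 0.2),
                                 ColoredNoiseParams(0.35, 0.15, 0.1, 0.2))["lnT_kramers"],
        },
    ),
    "fig19": dict(
        settings="ln T (Kramers) vs Q; D2=0.35, lambda2=0.1, tau=0.2; "
                 "(a) beta=0.2, alpha in {0.25, 0.3, 0.35}; (b) alpha=0.3, beta in {0.15, 0.25}",
        build=lambda seed: {
            "lnT_a": _stat_sweep("lnT_kramers", "Q", _Q_GRID, "alpha", [0.25, 0.3, 0.35],
                                 GompertzParams(0.25, 0.2),
                                 ColoredNoiseParams(0.35, 0.15, 0.1, 0.2))["lnT_kramers"],
            "lnT_b": _stat_sweep("lnT_kramers", "Q", _Q_GRID, "beta", [0.15, 0.25],
                                 GompertzParams(0.3, 0.2),
                                 ColoredNoiseParams(0.35, 0.15, 0.1, 0.2))["lnT_kramers"],
        },
    ),
    "fig20": dict(
        settings="ln T (Kramers) vs Q; D2=0.35, alpha=0.25, beta=0.2; "
                 "(a) lambda2 in {0, 0.3, 0.6} at tau=0.2; (b) tau in {0.1, 0.2, 0.4} at lambda2=0.1",
        build=lambda seed: {
            "lnT_a": _stat_sweep("lnT_kramers", "Q", _Q_GRID, "lambda2", [0.0, 0.3, 0.6],
                                 GompertzParams(0.25, 0.2),
                                 ColoredNoiseParams(0.35, 0.15, 0.1, 0.2))["lnT_kramers"],
            "lnT_b": _stat_sweep("lnT_kramers", "Q", _Q_GRID, "tau", [0.1, 0.2, 0.4],
                                 GompertzParams(0.25, 0.2),
                                 ColoredNoiseParams(0.35, 0.15, 0.1, 0.2))["lnT_kramers"],
        },
    ),
    "fig21": dict(
        settings="stationary mean <x> vs D2; Q=0.15, lambda2=0.1, tau=0.2; "
                 "(a) beta=0.2, alpha in {0.2, 0.25, 0.3}; (b) alpha=0.3, beta in {0.15, 0.2, 0.25}",
        build=lambda seed: {
            "mean_a": _stat_sweep("mean", "D2", _D2_MOMENT_GRID, "alpha", [0.2, 0.25, 0.3],
                                  GompertzParams(0.25, 0.2),
                                  ColoredNoiseParams(0.35, 0.15, 0.1, 0.2))["mean"],
            "mean_b": _stat_sweep("mean", "D2", _D2_MOMENT_GRID, "beta", [0.15, 0.2, 0.25],
                                  GompertzParams(0.3, 0.2),
                                  ColoredNoiseParams(0.35, 0.15, 0.1, 0.2))["mean"],
        },
    ),
    "fig22": dict(
        settings="stationary mean <x> vs D2; alpha=0.25, beta=0.2, Q=0.15; "
                 "(a) lambda2 in {0, 0.3, 0.6, 0.9} at tau=0.2; (b) tau in {0.1, 0.2, 0.4} at lambda2=0.1",
        build=lambda seed: {
            "mean_a": _stat_sweep("mean", "D2", _D2_MOMENT_GRID, "lambda2", [0.0, 0.3, 0.6, 0.9],
                                  GompertzParams(0.25, 0.2),
                                  ColoredNoiseParams(0.35, 0.15, 0.1, 0.2))["mean"],
            "mean_b": _stat_sweep("mean", "D2", _D2_MOMENT_GRID, "tau", [0.1, 0.2, 0.4],
                                  GompertzParams(0.25, 0.2),
                                  ColoredNoiseParams(0.35, 0.15, 0.1, 0.2))["mean"],
        },
    ),
    "fig23": dict(
        settings="normalized variance sigma2 vs D2; Q=0.15, lambda2=0.1, tau=0.2; "
                 "(a) beta=0.2, alpha in {0.2, 0.25, 0.3}; (b) alpha=0.3, beta in {0.15, 0.2, 0.25}",
        build=lambda seed: {
            "var_a": _stat_sweep("variance_norm", "D2", _D2_MOMENT_GRID, "alpha",
                                 [0.2, 0.25, 0.3], GompertzParams(0.25, 0.2),
                                 ColoredNoiseParams(0.35, 0.15, 0.1, 0.2))["variance_norm"],
            "var_b": _stat_sweep("variance_norm", "D2", _D2_MOMENT_GRID, "beta",
                                 [0.15, 0.2, 0.25], GompertzParams(0.3, 0.2),
                                 ColoredNoiseParams(0.35, 0.15, 0.1, 0.2))["variance_norm"],
        },
    ),
    "fig24": dict(
        settings="normalized variance sigma2 vs D2; alpha=0.25, beta=0.2, Q=0.15; "
                 "(a) lambda2 in {0, 0.3, 0.6, 0.9} at tau=0.2; (b) tau in {0.1, 0.2, 0.4} at lambda2=0.1",
        build=lambda seed: {
            "var_a": _stat_sweep("variance_norm", "D2", _D2_MOMENT_GRID, "lambda2",
                                 [0.0, 0.3, 0.6, 0.9], GompertzParams(0.25, 0.2),
                                 ColoredNoiseParams(0.35, 0.15, 0.1, 0.2))["variance_norm"],
            "var_b": _stat_sweep("variance_norm", "D2", _D2_MOMENT_GRID, "tau",
                                 [0.1, 0.2, 0.4], GompertzParams(0.25, 0.2),
                                 ColoredNoiseParams(0.35, 0.15, 0.1, 0.2))["variance_norm"],
        },
    ),
    "fig25": dict(
        settings="normalized skewness sigma3 vs D2; Q=0.15, lambda2=0.1, tau=0.2; "
                 "(a) beta=0.2, alpha in {0.2, 0.25, 0.3}; (b) alpha=0.3, beta in {0.15, 0.2, 0.25}",
        build=lambda seed: {
            "skew_a": _stat_sweep("skewness_norm", "D2", _D2_MOMENT_GRID, "alpha",
                                  [0.2, 0.25, 0.3], GompertzParams(0.25, 0.2),
                                  ColoredNoiseParams(0.35, 0.15, 0.1, 0.2))["skewness_norm"],
            "skew_b": _stat_sweep("skewness_norm", "D2", _D2_MOMENT_GRID, "beta",
                                  [0.15, 0.2, 0.25], GompertzParams(0.3, 0.2),
                                  ColoredNoiseParams(0.35, 0.15, 0.1, 0.2))["skewness_norm"],
        },
    ),
    "fig26": dict(
        settings="normalized skewness sigma3 vs D2; alpha=0.25, beta=0.2, Q=0.15; "
                 "(a) lambda2 in {0, 0.3, 0.6, 0.9} at tau=0.2; (b) tau in {0.1, 0.2, 0.4} at lambda2=0.1",
        build=lambda seed: {
            "skew_a": _stat_sweep("skewness_norm", "D2", _D2_MOMENT_GRID, "lambda2",
                                  [0.0, 0.3, 0.6, 0.9], GompertzParams(0.25, 0.2),
                                  ColoredNoiseParams(0.35, 0.15, 0.1, 0.2))["skewness_norm"],
            "skew_b": _stat_sweep("skewness_norm", "D2", _D2_MOMENT_GRID, "tau",
                                  [0.1, 0.2, 0.4], GompertzParams(0.25, 0.2),
                                  ColoredNoiseParams(0.35, 0.15, 0.1, 0.2))["skewness_norm"],
        },
    ),
}


def figure_settings(fig_id: str) -> str:
    if fig_id not in FIGURES:
        raise KeyError(f"unknown figure id {fig_id!r}; known: {sorted(FIGURES)}")
    return FIGURES[fig_id]["settings"]


def reproduce_figure(fig_id: str, seed: int = 0) -> dict:
    """Return {curve_name: DataFrame} for the requested figure."""
    if fig_id not in FIGURES:
        raise KeyError(f"unknown figure id {fig_id!r}; known: {sorted(FIGURES)}")
    return FIGURES[fig_id]["build"](seed)
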