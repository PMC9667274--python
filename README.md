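# gompertz-sde

Stochastic dynamics of the improved Gompertz tumor-growth law

```
dx/dt = α·x − β·x·ln x,        α, β > 0,
```

where `x` is the tumor-cell number, `α` the birth rate and `β` the death
rate. The deterministic law has a single attracting state `xs = exp(α/β)`.
The package studies what happens when the growth is disturbed by noise:

* **Correlated white noise** — a multiplicative term `x·ε(t)` (intensity
  `D1`, modelling therapies and other external factors) plus an additive term
  `Λ(t)` (intensity `Q`, modelling the cellular environment), cross-correlated
  with coefficient `λ1 ∈ [−1, 1]`.
* **Colored (Ornstein–Uhlenbeck) multiplicative noise** — autocovariance
  `(D2/τ)·exp(−|t−s|/τ)` with correlation time `τ`, coupled to the additive
  white noise with coefficient `λ2`. The joint process is reduced to a
  one-dimensional Markov diffusion by the unified colored-noise approximation
  (UCNA), giving the effective drift and diffusion

  ```
  G(x) = (αx − βx ln x)/(1+τβ) + (D2 x + λ2√(D2 Q))/(1+τβ)²
  H(x) = (D2 x² + 2 λ2 √(D2 Q) x + Q)/(1+τβ)²
  ```

For either model the stationary probability density is the zero-flux
Fokker–Planck solution `P_st(x) = N/B(x) · exp(∫ A/B dx)` (`A`,`B` or `G`,`H`).
The package provides it in two forms — an elementary **closed form** (the
x·ln x drift replaced by its second-order Taylor substitute about x = 1,
valid on a truncation window) and an exact **quadrature** form — together
with the modified potentials `Φ = −∫(drift/diffusion) dx`, the density
extremum condition `G(x_m) − H′(x_m) = 0`, a Langevin simulator with
correlated noise increments, mean first-passage times (exact double integral
and Kramers steepest-descent form), and stationary moment statistics
(mean, normalized variance `σ² = ⟨x²⟩/⟨x⟩² − 1`, normalized skewness
`σ³ = ⟨x³⟩/⟨x⟩³ − 3σ² − 1`).

Intended users: researchers in mathematical oncology and stochastic
population dynamics who need a tested reference implementation of this model
family — the analytic formulas cross-validated against independent numerical
oracles, and a reproducible simulator.

## Worked example

```python
import gompertz_sde as g

gp = g.GompertzParams(alpha=0.25, beta=0.2)
cp = g.ColoredNoiseParams(D2=0.35, Q=0.15, lambda2=0.1, tau=0.2)

g.stable_state(gp)                      # 3.4903429574618414
g.relaxation_time(gp, 1.0, 0.003)       # 30.153923316230806

dens = g.spd_colored(gp, cp, method="quadrature")
dens.mode()                             # 0.5262234977904527
g.stationary_moment(dens, 1)            # 3.1853842075575587
g.normalized_variance(dens)             # 0.6470111348570662

g.mfpt_integral(gp, cp).T               # 4.059570267390701

cfg = g.SimConfig(dt=0.002, n_steps=100_000, n_paths=512, seed=1,
                  scheme="ucna_reference")
fp = g.first_passage_sample(gp, cp, cfg, 1.0, g.stable_state(gp))
fp.mean, fp.std_error                   # (4.2439, 0.1910)
```

Reading the numbers: the deterministic trajectory started from a single cell
reaches 99.7% of its carrying level `e^{1.25} ≈ 3.49` at `t ≈ 30.2` time
units. Under the colored/white noise mix the stationary cell-number
distribution peaks at `x ≈ 0.53` (noise pushes the bulk of probability far
below the deterministic equilibrium) with stationary mean 3.19 and relative
variance 0.65. The mean time for a population to first climb from the
reference state `x = 1` to the deterministic level `xs` is 4.06 time units by
the exact double-integral formula; direct simulation of 512 first-passage
paths gives 4.24 ± 0.19, consistent within Monte-Carlo error.

## Command-line interface

```bash
gompertz-sde spd       --alpha 0.3 --beta 0.1 --noise-kind white -D 0.25 -Q 0.15 --lam 0.2 --out run/
gompertz-sde mfpt      --alpha 0.25 --beta 0.2 -D 0.35 -Q 0.15 --lam 0.1 --tau 0.2 --method integral --out run/
gompertz-sde simulate  --alpha 0.25 --beta 0.2 -D 0.35 -Q 0.15 --tau 0.2 --scheme corrected --out run/
gompertz-sde sweep     --alpha 0.25 --beta 0.2 -D 0.35 -Q 0.15 --lam 0.1 --tau 0.2 \
                       --quantity lnT_kramers --parameter D2 --values 0.2,0.3,0.4 --out run/
gompertz-sde reproduce-figure fig3 --out figures/
```

Every command writes CSV/JSON outputs plus a `manifest.json` (tool version,
resolved configuration, seed, wall time) sufficient to reproduce the run;
`reproduce-figure fig1 … fig26` regenerates the published parameter sweeps
as tidy CSV curves and echoes the caption-sourced settings it used.
Parameters may also come from a YAML config file (`--config`), with flags
taking precedence.

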