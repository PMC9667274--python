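# Methods

## Model

The growth law is `dx/dt = α x − β x ln x` for the tumor-cell number
`x > 0`, with birth rate `α > 0` and death rate `β > 0` (both per unit time;
`x` and time are dimensionless model units throughout). Its closed-form
solution is `ln x(t) = α/β + (ln x0 − α/β) e^{−βt}`, a monotone approach to
the single attracting state `xs = e^{α/β}`. The dynamics is the gradient flow
of `V(x) = −((2α+β)/4) x² + (β/2) x² ln x` with the standard convention
`F(x) = −V′(x)`; some presentations print the relation without the minus
sign, but `V` as written has its minimum at `xs` only under the gradient
convention, which this package enforces (a unit test differentiates `V`
numerically against the drift). `x = 1` is *not* a fixed point
(`F(1) = α ≠ 0`); it is used purely as the reference start state of the
first-passage analyses.

The closed-form solver is canonical; adaptive ODE integration appears only
as a test oracle. The relaxation time to a relative tolerance band
`|x − xs| ≤ rtol·xs` is solved analytically from the closed form
(`t = ln(|α/β − ln x0| / δ)/β` with `δ = −ln(1−rtol)` from below,
`ln(1+rtol)` from above). At the benchmark rates `α = 0.25, β = 0.2`,
`x0 = 1`, `rtol = 0.003` this gives `t = 30.154`.

## Noise models and stationary densities

Two Langevin extensions are treated:

* white–white: `dx/dt = F(x) + x ε(t) + Λ(t)` with
  `⟨ε ε⟩ = 2D1 δ`, `⟨Λ Λ⟩ = 2Q δ`, `⟨ε Λ⟩ = 2λ1 √(D1 Q) δ`;
* colored–white: the multiplicative noise is an Ornstein–Uhlenbeck process
  `ξ(t)` with autocovariance `(D2/τ) e^{−|t−s|/τ}` (so `D2` is the
  integrated intensity and the white-noise limit `τ → 0` matches the first
  model with `D1 ↦ D2`), reduced by the unified colored-noise approximation
  (UCNA) to a one-dimensional Markov diffusion with drift `G` and diffusion
  `H` carrying the `(1+τβ)` factors.

Both cases share one algebraic core: `G/H = Ã/B̃` where `Ã`, `B̃` are the
white-noise drift/diffusion evaluated at the *effective rates*
`α̃ = α(1+τβ)`, `β̃ = β(1+τβ)` with the noise parameters unchanged. The
implementation exploits this; as a consequence the `τ = 0` reduction to the
white-noise theory is exact to machine precision, including normalization.

The stationary density is the zero-flux Fokker–Planck solution
`P_st = N/B · exp(∫ A/B dx)`, provided by two methods:

* **`quadrature` (exact reference).** The inner integral `∫ A/B` keeps the
  exact `x ln x` and is accumulated by composite Simpson quadrature on a
  dense grid from the reference point `x_ref = 1` (where `ln x = 0`), then
  interpolated monotonically (PCHIP). Tails decay like
  `exp(−β̃ (ln x)²/2D)` — normalizable on arbitrarily wide windows.
* **`closed_form`.** `∫ A/B` becomes elementary once `ln x` is replaced by
  its second-order Taylor polynomial about `x = 1`, i.e.
  `x ln x ↦ p(x) = −x³/2 + 2x² − 3x/2`. A sympy derivation (frozen into the
  test suite) shows the published coefficient set `f, C, E` satisfies
  `A_poly = C·B′ + f′·B + E` *exactly* under this substitution — this pins
  down both the approximation used and the density exponent: consistency
  with the defining integral requires `P_st ∝ B^{C−1} exp[f + arctan term]`
  (the exponent is sometimes printed as `C − ½`, which is incompatible with
  the definitions; this package uses `C − 1`). The `|λ| = 1` branch is
  degenerate (`B = u²` with `u = √D·x + sign(λ)√Q`) and its constants were
  re-derived from the defining integral; the same symbolic identity gates
  them. For `λ = −1` the diffusion vanishes at `x = √(Q/D)` and the closed
  form is singular there — supported algebraically but not recommended.

The polynomial substitute reverses the sign of the confinement far from
`x = 1` (`−β p(x) ~ +βx³/2`), so the closed form **diverges** at large `x`
and is normalizable only on a truncation window. The default window is
`[0, 10]`, covering the published plotting range; the normalization constant
is always computed over the window actually used and recorded in the density
metadata. Construction raises a `DivergenceError` when the log-density is
non-finite on the window or grows without bound toward its right edge with
an overflow-scale spread.

Evaluation grids are linear up to `x = 8` and geometric beyond, so very wide
supports (needed for untruncated moments) keep resolution near the origin.
Normalization uses adaptive quadrature split per decade. Normalization
accuracy is well inside the 1e−6 tolerance asserted by the tests. Density
modes are refined by root-finding on the derivative of a (non-shape-limited)
cubic-spline interpolant of the log-density; PCHIP would flatten slopes
exactly at the maximum.

## Density extrema

Interior extrema of the stationary density satisfy `G(x_m) − H′(x_m) = 0`
(zero-flux condition). At `λ2 = 0` this solves in closed form:
`x_m = exp[(α − D2/(1+τβ))/β]`. The published extremum equation carries the
cross term with the opposite sign (`+λ2√(D2 Q)` where differentiation gives
`−λ2√(D2 Q)`); both variants are implemented (`variant="derived"` canonical,
`variant="printed"` for comparison) and the suite quantifies the gap between
their roots. Note the published extremum *trends* in `Q` and `λ2` (`x_m`
rising with both) hold only for the printed variant; the derived equation
gives the opposite direction for those two parameters, while the `D2` and
`τ` directions agree between variants. With a positive cross-correlation the
exact density also develops a thin boundary layer at `x = 0` (it is
decreasing at the origin), and for sufficiently strong noise the interior
extremum disappears entirely and the density becomes boundary-peaked —
brackets passed to the root finder should sit above the boundary layer.

## Langevin simulator (synthetic-data generator)

Per time step, two correlated Gaussian increments are built from one pair of
standard normals: `U = √(2 D2 Δt)·ω`, `V = √(2 Q Δt)·(λ2 ω + √(1−λ2²) ξ)`,
so `corr(U, V) = λ2`. Three schemes integrate the two-dimensional system
`(x, ξ)` or its UCNA reduction:

* `printed_rk4` — an archival transcription of the published stochastic
  Runge–Kutta step. As printed, the multiplicative-scale increment `U` is
  added to the `x` update and `V/τ` to the `ξ` update (the roles the
  increment construction assigns are swapped), noise enters the interior
  Runge–Kutta stages, and the fourth `x`-stage reuses `Δt·h3` in its `ξ`
  argument where the pattern implies `Δt·k3` (even its noise-free step
  therefore differs from classical RK4 by exactly
  `(Δt/6)(x + Δt·h3)(Δt·h3)`, which a test asserts). Its stationary
  statistics do **not** converge to the model's; it is kept because it is
  evidently the program behind the published moment sweeps (below).
* `corrected` — classical RK4 on the coupled drift plus the increments in
  their consistent roles (`V` to `x`, `U/τ` to `ξ`). The `ξ`-marginal is a
  stationary OU process with variance `D2/τ` and autocorrelation `e^{−s/τ}`
  (tested); stationary `x`-statistics converge to the model's as `Δt → 0`.
* `ucna_reference` — Euler–Maruyama for the Itô diffusion
  `dx = G dt + √(2H) dW`, whose stationary density is *exactly* the analytic
  colored-noise density: the simulation oracle for every analytic result.

`x` is floored at `1e−8` because `ln x` is evaluated in every stage; floor
hits are counted and a clip rate above 1% of steps raises a warning naming
`Δt` as the likely cause. Each path owns a generator seeded by
`(master seed, path index)`, so ensembles are bit-reproducible and
independent of chunking. Default burn-in is half the step count; stationary
sampling uses a recording stride (`thin`) to bound memory.

First-passage sampling records, per path, the first time `x ≥ x_target`
(upward passage from `x_start`), linearly interpolated within the crossing
step to reduce discretization bias; non-arriving paths are censored and
reported. At the benchmark parameters (`α=0.25, β=0.2, D2=0.35, Q=0.15,
λ2=0.1, τ=0.2`), `Δt = 0.002` makes the simulated mean indistinguishable
from the exact value within Monte-Carlo error at ~2000 paths.

## First-passage times and moments

`mfpt_integral` evaluates `T = ∫_{xu}^{xs} dx/(H P_st) ∫_0^x P_st dy` by
nested quadrature against a quadrature-method density (exact for the reduced
diffusion with reflecting boundary at 0 — which the positivity floor
emulates). `mfpt_kramers` uses
`T ≈ 2π/√|β² − αβ| · exp[Φ2(1) − Φ2(xs)]` with the closed-form `Φ2`, whose
additive constants cancel in the difference; the curvatures `V″(1) = β − α`
and `V″(xs) = β` are verified symbolically. The curvature prefactor is read
as `2π/√|β²−αβ|` (standard Kramers form); the literal no-square-root reading
is available behind `sqrt_prefactor=False`. `lnT` is always `ln` of the
computed `T`. The Kramers value is a steepest-descent estimate and differs
from the exact integral by orders of magnitude at these noise levels (the
barrier is not small against the noise); only trend directions are
comparable.

Raw moments `⟨x^k⟩` are computed by composite Simpson on the density's own
evaluation grid, with every integrand sharing one quadrature rule — this
makes the two printed forms of the normalized variance
(`⟨(x−⟨x⟩)²⟩/⟨x⟩²` and `⟨x²⟩/⟨x⟩² − 1`) agree to 1e−10 by construction,
which `normalized_variance` asserts on every call. Moments default to the
shared `[0, 10]` truncation window; `wide_support_domain(gp, cp, k)` returns
a window wide enough that the order-`k` moment is effectively untruncated
(the stationary log-state is approximately Gaussian with variance
`σ_u² = D2/(β(1+τβ))` around `α/β`, and the `k`-th moment integrand peaks
near `ln x = α/β + k σ_u²`). `sweep(..., domain="wide")` selects it
per parameter set.

## Reported trends: what reproduces, what does not, and why

The published study prints parameter sets and curve directions rather than
numeric tables. The suite reproduces those directions, but several of them
are properties of the *published computations* rather than of the model, and
the package documents the distinction rather than hiding it:

* **Density mode vs α and β** — reproduced by the exact (quadrature)
  density: mode moves right as `α` grows, left as `β` grows.
* **Peak height vs `D1`** — the exact density's peak *rises* with `D1`
  (probability mass concentrates toward `x = 0`); the falling peak in the
  published sweep is reproduced by the closed form normalized on the shared
  window, whose `exp(+β̃x²/4D)` tail weakens as `D1` grows. The trend test
  uses the closed form, i.e. the object the published curves plot.
* **Extremum location `x_m`** — falls with `D2` (both equation variants),
  rises with `τ` (both); rises with `Q` and `λ2` only for the printed-sign
  variant, which the trend tests therefore use. The reported *shape in `β`*
  ("decreasing then flat" for moderate `D2`) does not verify: the `λ2 = 0`
  closed form `x_m = exp[(α − D2/(1+τβ))/β]` is increasing in `β` whenever
  `D2 > α(1+τβ)`, which covers the quoted `D2` range; the figure-reproduction
  command emits the computed (rising) curves.
* **`ln T` vs `D2` and `Q`** — monotone decreasing for both the Kramers and
  the integral method: reproduced as stated. The published claim that larger
  `τ` *accelerates* the transition does not verify: both methods give `ln T`
  increasing with `τ`, because `(1+τβ)` suppresses the effective diffusion.
  (The published `τ`-claims are internally inconsistent as well: the
  extremum sweep has `x_m` rising with `τ` while the density sweep narrative
  has the peak moving toward 0 with `τ`.)
* **Mean vs `D2`** — the stationary mean rises with `D2` only on effectively
  unbounded support (`⟨x⟩ ≈ exp(α/β + σ_u²/2 + …)`); on the shared
  truncation window the truncated mean falls. The trend test uses the wide
  support. The near-insensitivity of the mean to `λ2` and `τ` holds on the
  shared window (spread < 5%); on full support the `λ2` spread grows to
  ~10% — small against the `α`, `β`, `D2` effects, but not under 5%.
* **Humped `σ²`/`σ³` vs `D2`** — *not* a property of the stationary density
  under any convention tested (closed-form or quadrature, truncated or full
  support): both moments are monotone increasing in `D2`. The humps are
  reproduced exactly by stationary samples of the `printed_rk4` scheme —
  the published integrator — whose noise-role swap turns the multiplicative
  channel into an additive one. The trend test runs that scheme (fixed
  seed); a separate test asserts the density-based monotonicity.

## Validation tolerances and problem sizes

Analytic identities are tested at 1e−9 to 1e−14; density normalization at
1e−6; the white-noise limit at 1e−10 relative. Monte-Carlo comparisons use a
Kolmogorov–Smirnov distance of 0.02 for the reduced-diffusion integrator
(2×10⁵ stationary samples, `Δt = 0.005`, measured distance ≈ 0.006) and
0.05 for the corrected two-dimensional scheme at `τ = 0.1` (UCNA is an
approximation); the first-passage comparison uses 3 Monte-Carlo standard
errors over ≥ 2000 uncensored paths. Ensemble sizes (hundreds of paths,
10⁴–10⁵ steps) were chosen so the whole suite runs on one CPU in a few
minutes while keeping Monte-Carlo error well below each tolerance.

## What the generator does and does not emulate

The simulator generates trajectories of the *model* — growth with stationary
Gaussian (white or OU) perturbations, a positivity floor, and stationarity
after burn-in. It does not emulate features of real tumor data: measurement
error, sampling irregularity, inter-patient parameter variability, treatment
schedules, or extinction (absorbing `x → 0`). Passing tests therefore
demonstrate internal consistency of analytics and simulation, not biological
validity of the growth law.

## Known limitations

* UCNA validity is not policed; a warning is logged when `τβ > 1`.
* The closed-form density is meaningful only on its truncation window, and
  at small `β` (weak confinement) its divergent tail can dominate any window
  — the quadrature method is the reference whenever accuracy matters.
* `λ = −1` closed forms are provided for completeness but are singular at
  `x = √(Q/D)`.
* Downhill passages (`xs → xu`) and periodically forced escape are out of
  scope.
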