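import math

import numpy as np
import pytest
from scipy.stats import ks_1samp

from gompertz_sde import (
    ColoredNoiseParams,
    GompertzParams,
    SimConfig,
    draw_increments,
    empirical_density,
    first_passage_sample,
    simulate,
    solve_deterministic,
    spd_colored,
    step_corrected,
    step_printed_rk4,
    step_ucna_reference,
)
from gompertz_sde.langevin_sim import noise_drift


class TestNoiseIncrements:
    def test_moments_and_correlation(self):
        rng = np.random.default_rng(42)
        n, dt, D, Q, lam = 1_000_000, 0.01, 0.35, 0.15, 0.2
        inc = draw_increments(n, dt, D, Q, lam, rng)
        su, sv = math.sqrt(2 * D * dt), math.sqrt(2 * Q * dt)
        assert abs(inc.U.mean()) < 4 * su / math.sqrt(n)
        assert abs(inc.V.mean()) < 4 * sv / math.sqrt(n)
        assert inc.U.var() == pytest.approx(su**2, rel=0.01)
        assert inc.V.var() == pytest.approx(sv**2, rel=0.01)
        corr = np.corrcoef(inc.U, inc.V)[0, 1]
        assert corr == pytest.approx(lam, abs=0.004)  # Fisher-z bound at n=1e6

    def test_perfect_correlation_degenerates(self):
        rng = np.random.default_rng(0)
        inc = draw_increments(1000, 0.01, 0.35, 0.15, 1.0, rng)
        ratio = inc.V / inc.U
        assert np.allclose(ratio, ratio[0])

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError):
            draw_increments(10, 0.01, 0.35, 0.15, 1.5, np.random.default_rng(0))


class TestSteps:
    def test_stage_values(self, gp):
        # drift field at x=1 with xi=0.5: ln 1 = 0 so h1 = alpha + 0.5
        assert noise_drift(1.0, 0.5, gp) == pytest.approx(gp.alpha + 0.5, abs=1e-15)
        # first xi stage: k1 = -xi/tau
        assert -0.3 / 0.2 == pytest.approx(-1.5)

    def test_corrected_noise_free_step_is_classical_rk4(self, gp):
        cp = ColoredNoiseParams(0.35, 0.15, 0.1, 0.2)
        dt = 0.01
        x1, xi1 = step_corrected(1.0, 0.0, gp, cp, dt, 0.0, 0.0)
        exact = solve_deterministic(gp, 1.0, [0.0, dt]).values[-1]
        assert xi1 == 0.0
        assert x1 == pytest.approx(exact, abs=10 * dt**5)

    def test_printed_fourth_stage_slip_is_preserved(self, gp):
        """The archival step reuses dt*h3 in the xi slot of its fourth stage,
        so even the noise-free update differs from classical RK4 by exactly
        (dt/6) * (x + dt*h3) * (dt*h3)."""
        cp = ColoredNoiseParams(0.35, 0.15, 0.1, 0.2)
        dt = 0.01
        for x0 in (1.0, 2.0):
            xp, _ = step_printed_rk4(x0, 0.0, gp, cp, dt, 0.0, 0.0)
            xc, _ = step_corrected(x0, 0.0, gp, cp, dt, 0.0, 0.0)
            h1 = noise_drift(x0, 0.0, gp)
            h2 = noise_drift(x0 + 0.5 * dt * h1, 0.0, gp)
            h3 = noise_drift(x0 + 0.5 * dt * h2, 0.0, gp)
            slip = (dt / 6.0) * (x0 + dt * h3) * (dt * h3)
            assert xp - xc == pytest.approx(slip, rel=1e-10)

    def test_zero_correlation_time_rejected(self, gp):
        cp = ColoredNoiseParams(0.35, 0.15, 0.1, 0.0)
        with pytest.raises(ValueError, match="tau"):
            step_printed_rk4(1.0, 0.0, gp, cp, 0.01, 0.0, 0.0)
        with pytest.raises(ValueError, match="tau"):
            step_corrected(1.0, 0.0, gp, cp, 0.01, 0.0, 0.0)

    def test_ucna_step_deterministic_without_noise(self, gp):
        cp = ColoredNoiseParams(0.0, 0.0, 0.0, 0.2)
        rng = np.random.default_rng(1)
        x1 = step_ucna_reference(1.0, gp, cp, 0.01, rng)
        from gompertz_sde import drift_G
        assert x1 == pytest.approx(1.0 + 0.01 * drift_G(1.0, gp, cp), abs=1e-15)


class TestSimulate:
    def test_seed_reproducibility(self, gp, cp_bench):
        cfg = SimConfig(dt=0.01, n_steps=500, n_paths=8, seed=123, scheme="corrected",
                        record_xi=True)
        e1 = simulate(gp, cp_bench, cfg)
        e2 = simulate(gp, cp_bench, cfg)
        assert np.array_equal(e1.values, e2.values)
        assert np.array_equal(e1.xi, e2.xi)
        e3 = simulate(gp, cp_bench, SimConfig(dt=0.01, n_steps=500, n_paths=8, seed=124,
                                              scheme="corrected"))
        assert not np.array_equal(e1.values, e3.values)

    def test_noise_free_config_rises_monotonically_to_stable_state(self, gp):
        cp = ColoredNoiseParams(0.0, 0.0, 0.0, 0.2)
        cfg = SimConfig(dt=0.01, n_steps=6000, n_paths=1, seed=0, scheme="corrected")
        ens = simulate(gp, cp, cfg)
        x = ens.values[0]
        assert np.all(np.diff(x) > -1e-14)
        assert x[-1] == pytest.approx(gp.stable_state, rel=1e-3)

    def test_noisy_paths_fluctuate_about_deterministic_solution(self, gp, cp_bench):
        cfg = SimConfig(dt=0.01, n_steps=6000, n_paths=32, seed=3, scheme="corrected",
                        thin=10)
        ens = simulate(gp, cp_bench, cfg)
        det = solve_deterministic(gp, 1.0, ens.times).values
        late = ens.times > 30
        resid = ens.values[:, late] - det[late]
        # centered near the deterministic branch but genuinely fluctuating
        assert abs(resid.mean()) < 3 * resid.std()
        assert resid.std() > 0.1

    def test_xi_marginal_is_ou_stationary(self, gp, cp_bench):
        """Corrected scheme: xi is a stationary OU process with variance
        D2/tau and autocovariance (D2/tau) exp(-s/tau)."""
        cfg = SimConfig(dt=0.01, n_steps=40_000, n_paths=16, seed=9,
                        scheme="corrected", thin=1, record_xi=True)
        ens = simulate(gp, cp_bench, cfg)
        xi = ens.xi[:, 20_000:]
        var_target = cp_bench.D2 / cp_bench.tau
        assert xi.mean() == pytest.approx(0.0, abs=4 * math.sqrt(var_target / 300))
        assert xi.var() == pytest.approx(var_target, rel=0.05)
        # autocorrelation at lag tau should be ~ e^-1
        lag = int(round(cp_bench.tau / cfg.dt))
        ac = np.mean([(np.corrcoef(p[:-lag], p[lag:])[0, 1]) for p in xi])
        assert ac == pytest.approx(math.exp(-1.0), abs=0.05)

    def test_dt_refinement_converges(self, gp, cp_bench):
        """Stationary mean from the corrected scheme is Cauchy in dt."""
        means = []
        for dt in (0.02, 0.01, 0.005):
            cfg = SimConfig(dt=dt, n_steps=int(200 / dt), n_paths=48, seed=21,
                            scheme="corrected", thin=max(1, int(0.5 / dt)))
            ens = simulate(gp, cp_bench, cfg)
            s = ens.stationary_samples()
            means.append(s.mean())
        se = 3 * np.std(s) / math.sqrt(s.size / 8)  # generous correlated-sample bound
        assert abs(means[2] - means[1]) < se
        assert abs(means[1] - means[0]) < 2 * se


class TestEmpiricalDensity:
    def test_unit_integral_and_unimodality(self, gp_growth, cp_overlay):
        cfg = SimConfig(dt=0.01, n_steps=20_000, n_paths=32, seed=17,
                        scheme="ucna_reference", thin=50)
        ens = simulate(gp_growth, cp_overlay, cfg)
        samples = ens.stationary_samples()
        assert samples.size >= 1000
        hist = empirical_density(samples, bins=40, domain=(0, 10))
        assert hist.integral() == pytest.approx(1.0, abs=1e-12)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            empirical_density([])

    def test_histogram_tracks_analytic_density(self, gp, cp_overlay):
        cfg = SimConfig(dt=0.005, n_steps=60_000, n_paths=64, seed=23,
                        scheme="ucna_reference", thin=100, burn_in=10_000)
        ens = simulate(gp, cp_overlay, cfg)
        dens = spd_colored(gp, cp_overlay, method="quadrature", domain=(0, 200),
                           grid_n=6001)
        res = ks_1samp(ens.stationary_samples(), dens.cdf)
        assert res.statistic < 0.05


class TestFirstPassage:
    def test_degenerate_target_gives_zero_times(self, gp, cp_bench):
        cfg = SimConfig(dt=0.01, n_steps=100, n_paths=16, seed=0, scheme="ucna_reference")
        fp = first_passage_sample(gp, cp_bench, cfg, 1.0, 1.0)
        assert np.all(fp.times == 0.0)
        assert fp.n_censored == 0

    def test_downward_passage_rejected(self, gp, cp_bench):
        cfg = SimConfig(dt=0.01, n_steps=100, n_paths=4, seed=0, scheme="ucna_reference")
        with pytest.raises(ValueError):
            first_passage_sample(gp, cp_bench, cfg, 2.0, 1.0)

    def test_all_censored_raises(self, gp):
        cp = ColoredNoiseParams(0.0, 1e-6, 0.0, 0.2)
        cfg = SimConfig(dt=0.001, n_steps=10, n_paths=8, seed=0, scheme="ucna_reference")
        with pytest.raises(RuntimeError, match="censored"):
            first_passage_sample(gp, cp, cfg, 1.0, 100.0)

    def test_additive_noise_accelerates_passage(self, gp):
        """Larger additive intensity Q shortens the mean passage time."""
        means = []
        for Q in (0.10, 0.25):
            cp = ColoredNoiseParams(0.35, Q, 0.1, 0.2)
            cfg = SimConfig(dt=0.004, n_steps=50_000, n_paths=512, seed=31,
                            scheme="ucna_reference")
            fp = first_passage_sample(gp, cp, cfg, 1.0, gp.stable_state)
            assert fp.n_censored == 0
            means.append(fp.mean)
        assert means[1] < means[0]
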