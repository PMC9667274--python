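import math

import numpy as np
import pytest
import sympy as sp

from gompertz_sde import (
    DivergenceError,
    GompertzParams,
    WhiteNoiseParams,
    closed_form_coefficients,
    diffusion_B,
    drift_A,
    modified_potential_white,
    spd_white,
)
from gompertz_sde import _closedform as cf
from gompertz_sde._closedform import ClosedFormUnsupported


class TestNoiseParams:
    @pytest.mark.parametrize("kw", [dict(D1=-0.1, Q=0.15), dict(D1=0.25, Q=-1.0),
                                    dict(D1=0.25, Q=0.15, lambda1=1.2)])
    def test_rejects_invalid(self, kw):
        with pytest.raises(ValueError):
            WhiteNoiseParams(**kw)


class TestDriftDiffusion:
    def test_drift_at_origin_is_cross_term(self):
        gp = GompertzParams(0.3, 0.1)
        wp = WhiteNoiseParams(0.25, 0.15, 0.2)
        assert drift_A(0.0, gp, wp) == pytest.approx(0.2 * math.sqrt(0.25 * 0.15),
                                                     abs=1e-15)

    def test_drift_at_one_uncorrelated(self):
        gp = GompertzParams(0.3, 0.1)
        wp = WhiteNoiseParams(0.25, 0.15, 0.0)
        assert drift_A(1.0, gp, wp) == pytest.approx(0.55, abs=1e-15)

    def test_drift_at_stable_state(self, gp):
        wp = WhiteNoiseParams(0.25, 0.15, 0.0)
        xs = gp.stable_state
        assert drift_A(xs, gp, wp) == pytest.approx(0.25 * xs, rel=1e-12)

    def test_diffusion_values(self):
        gp = GompertzParams(0.3, 0.1)
        assert diffusion_B(0.0, gp, WhiteNoiseParams(0.25, 0.15, 0.2)) == 0.15
        # perfect square at |lambda| = 1
        assert diffusion_B(2.0, gp, WhiteNoiseParams(0.25, 0.16, 1.0)) == pytest.approx(
            1.96, abs=1e-14)
        assert diffusion_B(1.0, gp, WhiteNoiseParams(0.25, 0.15, 0.2)) == pytest.approx(
            0.25 + 0.4 * math.sqrt(0.0375) + 0.15, abs=1e-15)

    def test_zero_correlation_decouples(self, gp):
        wp = WhiteNoiseParams(0.25, 0.15, 0.0)
        x = np.linspace(0, 8, 50)
        assert np.allclose(diffusion_B(x, gp, wp), 0.25 * x**2 + 0.15)
        base = GompertzParams(gp.alpha, gp.beta)
        assert np.allclose(
            drift_A(x[1:], base, wp),
            gp.alpha * x[1:] - gp.beta * x[1:] * np.log(x[1:]) + 0.25 * x[1:])


class TestClosedFormCoefficients:
    def test_printed_values_at_zero_correlation(self):
        gp = GompertzParams(0.3, 0.1)
        wp = WhiteNoiseParams(0.25, 0.15, 0.0)
        c = closed_form_coefficients(gp, wp)
        assert c.E == pytest.approx(2 * 0.1 * 0.15 / 0.25, abs=1e-15)   # 0.12
        assert c.f_lin == pytest.approx(-2 * 0.1 / 0.25, abs=1e-15)     # -0.8
        assert c.f_quad == pytest.approx(0.1 / (4 * 0.25), abs=1e-15)

    @pytest.mark.parametrize("lam", [-0.7, 0.0, 0.2, 0.9])
    def test_quadratic_coefficient_independent_of_correlation(self, lam):
        gp = GompertzParams(0.3, 0.1)
        c = closed_form_coefficients(gp, WhiteNoiseParams(0.25, 0.15, lam))
        assert c.f_quad == pytest.approx(0.1 / (4 * 0.25), abs=1e-15)
        assert c.branch == "subcritical"

    def test_zero_multiplicative_noise_unsupported(self, gp):
        with pytest.raises(ClosedFormUnsupported, match="quadrature"):
            closed_form_coefficients(gp, WhiteNoiseParams(0.0, 0.15, 0.0))

    def test_symbolic_identity_subcritical(self):
        """Master gate: the coefficients reproduce the defining integral.

        Symbolically, A_poly = C*B' + f'*B + E, where A_poly substitutes
        x ln x by x times the second-order Taylor polynomial of ln about 1.
        """
        x, a, b, D, Q = sp.symbols("x a b D Q", positive=True)
        lam = sp.Symbol("lam")
        r = sp.sqrt(D * Q)
        p = sp.expand(x * ((x - 1) - (x - 1) ** 2 / 2))
        A_poly = a * x - b * p + D * x + lam * r
        B = D * x**2 + 2 * lam * r * x + Q
        f = b / (4 * D) * x**2 - (2 * b / D + lam * b * r / D**2) * x
        C = (a / (2 * D) + 3 * b / (4 * D) + 2 * lam * b * r / D**2
             + (4 * lam**2 - 1) * b * Q / (4 * D**2) + sp.Rational(1, 2))
        E = ((2 - 4 * lam**2) * b * Q / D - (2 * a + 3 * b) * lam * r / (2 * D)
             + (3 - 4 * lam**2) * lam * b * Q * r / (2 * D**2))
        resid = sp.simplify(A_poly - (C * sp.diff(B, x) + sp.diff(f, x) * B + E))
        assert resid == 0

    @pytest.mark.parametrize("sgn", [1, -1])
    def test_symbolic_identity_critical(self, sgn):
        """|lambda| = 1 branch: A_poly = f'*u^2 + C*sqrt(D)*u + E*sqrt(D)."""
        x, a, b, D, Q = sp.symbols("x a b D Q", positive=True)
        p = sp.expand(x * ((x - 1) - (x - 1) ** 2 / 2))
        A_poly = a * x - b * p + D * x + sgn * sp.sqrt(D * Q)
        u = sp.sqrt(D) * x + sgn * sp.sqrt(Q)
        f = (b / (4 * D) * x**2 - (2 * b / D + sgn * b * sp.sqrt(Q) / D ** sp.Rational(3, 2)) * x)
        C = (1 + a / D + 3 * b / (2 * D) + 3 * Q * b / (2 * D**2)
             + 4 * sgn * sp.sqrt(Q) * b / D ** sp.Rational(3, 2))
        E = (-sgn * (sp.sqrt(Q) * a / D + 3 * sp.sqrt(Q) * b / (2 * D)
                     + Q ** sp.Rational(3, 2) * b / (2 * D**2))
             - 2 * Q * b / D ** sp.Rational(3, 2))
        resid = sp.simplify(A_poly - (sp.diff(f, x) * u**2 + C * sp.sqrt(D) * u
                                      + E * sp.sqrt(D)))
        assert resid == 0


def _log_density_derivative_residual(eff, x):
    """|d/dx ln Pst_closed - (A_poly/B - B'/B)| using analytic derivatives."""
    a, b, D, Q, lam = eff
    c = cf.coefficients(a, b, D, Q, lam)
    r = math.sqrt(D * Q)
    B = cf.diffusion(x, *eff)
    dB = 2 * D * x + 2 * lam * r
    if c.branch == "subcritical":
        deriv = (c.C - 1) * dB / B + 2 * c.f_quad * x + c.f_lin + c.E / B
    else:
        u = math.sqrt(D) * x + math.copysign(math.sqrt(Q), lam)
        deriv = ((c.C - 2) * math.sqrt(D) / u + 2 * c.f_quad * x + c.f_lin
                 + c.E * math.sqrt(D) / u**2)
    target = cf.drift_poly(x, *eff) / B - dB / B
    return np.abs(deriv - target)


class TestModifiedPotential:
    def test_differences_invariant_to_reference(self, gp, wp):
        x = np.linspace(0.5, 5, 20)
        p1 = modified_potential_white(x, gp, wp, method="quadrature", x_ref=1.0)
        p2 = modified_potential_white(x, gp, wp, method="quadrature", x_ref=2.0)
        d = p1 - p2
        assert np.allclose(d - d[0], 0.0, atol=1e-9)

    def test_closed_form_derivative_identity(self, gp, wp):
        xs = np.linspace(0.2, 6.0, 117)
        eff = wp.as_effective(gp)
        res = max(_log_density_derivative_residual(eff, float(x)) for x in xs)
        assert res < 1e-9

    def test_branch_continuity_toward_perfect_correlation(self, gp):
        x = np.linspace(0.5, 5.0, 101)
        near = modified_potential_white(x, gp, WhiteNoiseParams(0.25, 0.15, 0.999))
        crit = modified_potential_white(x, gp, WhiteNoiseParams(0.25, 0.15, 1.0))
        i0 = np.argmin(np.abs(x - 1.0))
        near = near - near[i0]
        crit = crit - crit[i0]
        assert np.max(np.abs(near - crit)) < 0.02

    def test_quadrature_matches_closed_form_where_polynomial_is_good(self, gp, wp):
        # near x = 1 the Taylor substitution is excellent, so the two
        # potentials agree after constant matching
        x = np.linspace(0.8, 1.2, 41)
        pc = modified_potential_white(x, gp, wp, method="closed_form")
        pq = modified_potential_white(x, gp, wp, method="quadrature")
        pc = pc - pc[20]
        pq = pq - pq[20]
        assert np.max(np.abs(pc - pq)) < 2e-4


class TestStationaryDensity:
    @pytest.mark.parametrize("method", ["closed_form", "quadrature"])
    def test_normalization(self, gp_growth, wp, method):
        dens = spd_white(gp_growth, wp, method=method)
        assert dens.integral() == pytest.approx(1.0, abs=1e-6)
        assert np.all(dens.evaluate(np.linspace(0, 10, 301)) >= 0)

    def test_quadrature_density_unimodal_after_origin_layer(self, gp_growth, wp):
        """Away from the thin boundary layer at 0, the exact density rises
        to a single maximum and then falls."""
        dens = spd_white(GompertzParams(0.35, 0.1), wp, method="quadrature",
                         domain=(0, 15))
        x = np.linspace(0.25, 15, 600)
        p = dens.evaluate(x)
        signs = np.sign(np.diff(p))
        changes = np.count_nonzero(np.diff(signs[signs != 0]) != 0)
        assert changes == 1

    def test_mode_shifts_right_with_birth_rate(self, wp):
        modes = [spd_white(GompertzParams(a, 0.1), wp, method="quadrature",
                           domain=(0, 15)).mode() for a in (0.25, 0.35, 0.45)]
        assert modes[0] < modes[1] < modes[2]

    def test_quadrature_tails_are_normalizable(self, gp, wp):
        """Doubling the window changes the normalization less and less."""
        z = []
        for hi in (20.0, 40.0, 80.0, 160.0):
            d = spd_white(gp, wp, method="quadrature", domain=(0, hi))
            z.append(d.log_norm)
        deltas = np.abs(np.diff(z))
        assert np.all(np.diff(deltas) < 0)
        assert deltas[-1] < 5e-3

    def test_closed_form_divergence_detected(self, gp_growth, wp):
        with pytest.raises((DivergenceError, OverflowError)):
            spd_white(gp_growth, wp, method="closed_form", domain=(0, 400))

    def test_csv_export_round_trip(self, gp_growth, wp, tmp_path):
        dens = spd_white(gp_growth, wp, method="quadrature")
        path = tmp_path / "spd.csv"
        dens.to_csv(path, grid=np.linspace(0, 10, 11))
        rows = path.read_text().strip().splitlines()
        assert rows[0] == "x,pst"
        assert len(rows) == 12
        dens.write_metadata(tmp_path / "spd.json")
        assert (tmp_path / "spd.json").exists()
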