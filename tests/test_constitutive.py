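"""Constitutive terms: mobilities, pressures, active stress, kinetics."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swarmdrop.constitutive import (active_stress, bacteria_rhs,
                                    capillary_pressure, chemo_rhs,
                                    disjoining_pressure, growth_term, mobility)
from swarmdrop.grid import Grid1D
from swarmdrop.params import reference_dimensionless


@pytest.fixture(scope="module")
def p():
    return reference_dimensionless()


class TestMobility:
    @pytest.mark.parametrize("h,slip,mp,ma", [
        (1.0, 0.0, 1.0 / 3.0, 0.5),       # no-slip Poiseuille limit
        (0.0, 0.3, 0.0, 0.0),             # dry point carries no flux
        (2.0, 0.5, 14.0 / 3.0, 3.0),      # analytic slip-parabola integral
    ])
    def test_analytic_values(self, h, slip, mp, ma):
        got = mobility(h, slip)
        assert got == pytest.approx((mp, ma), rel=1e-14)

    def test_negative_height_rejected(self):
        with pytest.raises(ValueError):
            mobility(-0.1, 0.0)

    @settings(deadline=None, max_examples=20)
    @given(h=st.floats(1e-3, 10.0), slip=st.floats(0.0, 2.0))
    def test_nonnegative_monotone_and_noslip_reduction(self, h, slip):
        mp, ma = mobility(h, slip)
        mp2, ma2 = mobility(h * 1.01, slip)
        assert mp >= 0 and ma >= 0
        assert mp2 > mp and ma2 > ma
        mp0, ma0 = mobility(h, 0.0)
        assert mp0 == pytest.approx(h**3 / 3, rel=1e-14)
        assert ma0 == pytest.approx(h**2 / 2, rel=1e-14)


class TestCapillaryPressure:
    def test_flat_film_has_zero_pressure(self):
        g = Grid1D.uniform(0, 10, 64)
        assert capillary_pressure(np.full(64, 0.7), g, 0.5) == pytest.approx(0.0)

    def test_linear_ramp_has_zero_pressure(self):
        g = Grid1D.uniform(0, 10, 64)
        p = capillary_pressure(0.3 * g.x, g, 0.5)
        assert np.abs(p[1:-1]).max() < 1e-10

    def test_cosine_against_spectral_oracle(self):
        # second-order convergence to the spectral derivative of cos(kx)
        k = 2 * np.pi / 10.0
        Ca = 0.4
        errs = []
        for n in (64, 128):
            g = Grid1D.uniform(0, 10 * (1 - 1 / n), n, boundary_kind="periodic")
            h = np.cos(k * g.x)
            exact = (k**2 / Ca) * np.cos(k * g.x)
            # independent oracle: FFT differentiation
            hk = np.fft.rfft(h)
            freq = 2 * np.pi * np.fft.rfftfreq(n, d=g.dx)
            spectral = -np.fft.irfft(-(freq**2) * hk, n) / Ca
            assert np.allclose(exact, spectral, atol=1e-10)
            errs.append(np.abs(capillary_pressure(h, g, Ca) - exact).max())
        assert errs[1] < errs[0] / 3.0  # ~ O(dx^2)

    def test_too_few_nodes_rejected(self):
        g = Grid1D.uniform(0, 1, 16)
        with pytest.raises(ValueError):
            capillary_pressure(np.ones(4), g, 1.0)


class TestActiveStress:
    def test_uniform_chemo_gives_zero_stress(self, p):
        g = Grid1D.uniform(0, 10, 64)
        assert np.all(active_stress(np.full(64, 2.0), g, p) == 0.0)

    def test_bounded_by_Ca_xi_and_saturating(self, p):
        g = Grid1D.uniform(0, 10, 256)
        c = 1e6 * g.x  # enormous gradient
        sig = active_stress(c, g, p)
        assert np.all(np.abs(sig) <= p.Ca_xi + 1e-12)
        assert sig[10] == pytest.approx(p.Ca_xi, rel=1e-4)

    def test_half_saturation_point(self, p):
        g = Grid1D.uniform(0, 10, 64)
        c = p.saturation * g.x  # dc/dx == saturation exactly
        sig = active_stress(c, g, p)
        assert sig[5] == pytest.approx(0.5 * p.Ca_xi, rel=1e-12)

    def test_odd_under_reflection(self, p):
        g = Grid1D.uniform(0, 10, 64)
        rng = np.random.default_rng(0)
        c = np.cumsum(rng.normal(size=64))
        np.testing.assert_allclose(active_stress(c, g, p),
                                   -active_stress(-c, g, p), atol=1e-14)

    def test_sensing_gate_zeroes_weak_gradients(self, p):
        g = Grid1D.uniform(0, 10, 64)
        c = 0.5 * p.sensing * g.x  # below threshold everywhere
        assert np.all(active_stress(c, g, p, gate_sensing=True) == 0.0)
        assert np.all(active_stress(c, g, p, gate_sensing=False) != 0.0)


class TestKinetics:
    def test_no_food_no_growth(self, p):
        h = np.linspace(p.precursor, 2.0, 32)
        assert np.all(growth_term(h, np.zeros(32), p) == 0.0)

    def test_no_growth_on_precursor_film(self, p):
        h = np.full(32, p.precursor)
        assert np.all(growth_term(h, np.ones(32), p) == 0.0)

    def test_growth_saturates_in_bacteria(self, p):
        h = np.full(8, 1.0)
        s = growth_term(h, np.full(8, 1e9), p)
        assert s == pytest.approx(p.growth * (1.0 - p.precursor), rel=1e-6)

    def test_no_consumption_without_cells_or_bacteria(self, p):
        h = np.full(16, p.precursor)
        assert np.all(bacteria_rhs(h, np.ones(16), p) == 0.0)
        assert np.all(bacteria_rhs(np.ones(16), np.zeros(16), p) == 0.0)

    def test_uniform_consumption_matches_exponential_decay(self, p):
        """Scalar-ODE closed form over 10 time units to 1e-6."""
        from scipy.integrate import solve_ivp

        b0 = 1.3
        h0 = p.precursor + 0.5 / p.consumption  # decay rate 0.5 per time unit
        rate = p.consumption * (h0 - p.precursor)
        sol = solve_ivp(lambda t, b: bacteria_rhs(np.full(1, h0), b, p),
                        (0, 10), [b0], rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(b0 * np.exp(-rate * 10), rel=1e-6)

    def test_chemo_pure_decay_closed_form(self, p):
        from scipy.integrate import solve_ivp

        g = Grid1D.uniform(0, 10, 32)
        c0 = 0.7
        sol = solve_ivp(
            lambda t, c: chemo_rhs(c, np.zeros(32), g, p),
            (0, 0.2), np.full(32, c0), rtol=1e-10, atol=1e-12)
        assert sol.y[:, -1] == pytest.approx(c0 * np.exp(-p.decay * 0.2), rel=1e-7)

    def test_chemo_uniform_fixed_point(self, p):
        g = Grid1D.uniform(0, 10, 32)
        b = np.full(32, 0.6)
        c_star = p.production * b / p.decay
        assert np.abs(chemo_rhs(c_star, b, g, p)).max() < 1e-12

    def test_chemo_screening_length_of_point_source(self, p):
        """Quasi-steady response to a localized source decays over
        sqrt(1/(peclet*decay)), matched against the analytic Green function."""
        g = Grid1D.uniform(0, 40, 2048)
        b = np.zeros(g.n)
        b[g.n // 2] = 1.0 / g.dx  # unit point mass
        # steady state: solve (D d2/dx2 - decay) c = -production*b
        from scipy.linalg import solve_banded

        D = 1.0 / p.peclet
        n = g.n
        ab = np.zeros((3, n))
        ab[0, 1:] = D / g.dx**2
        ab[2, :-1] = D / g.dx**2
        ab[1, :] = -2 * D / g.dx**2 - p.decay
        ab[0, 1] = 2 * D / g.dx**2
        ab[2, -2] = 2 * D / g.dx**2
        c = solve_banded((1, 1), ab, -p.production * b)
        assert np.abs(chemo_rhs(c, b, g, p)).max() < 1e-6 * c.max()
        ell = np.sqrt(1.0 / (p.peclet * p.decay))
        x0 = g.x[n // 2]
        sel = (g.x > x0 + 2 * ell) & (g.x < x0 + 6 * ell)
        slope = np.polyfit(g.x[sel], np.log(c[sel]), 1)[0]
        assert -1.0 / slope == pytest.approx(ell, rel=0.02)


def test_constitutive_terms_are_pure(p):
    g = Grid1D.uniform(0, 10, 64)
    rng = np.random.default_rng(1)
    h = 0.5 + 0.4 * np.sin(g.x) + p.precursor
    c = np.abs(np.cumsum(rng.normal(size=64))) * 0.01
    b = np.abs(rng.normal(size=64))
    for fn, args in [(capillary_pressure, (h, g, 0.3)),
                     (active_stress, (c, g, p)),
                     (growth_term, (h, b, p)),
                     (bacteria_rhs, (h, b, p)),
                     (chemo_rhs, (c, b, g, p)),
                     (disjoining_pressure, (h, p.precursor))]:
        a1, a2 = fn(*args), fn(*args)
        assert np.array_equal(a1, a2)


def test_disjoining_pressure_selects_unit_contact_angle(p):
    """The wetting potential integral fixes slope 1 at the contact line:
    integral of -Pi from precursor to infinity equals theta^2/2."""
    from scipy.integrate import quad

    hs = p.precursor
    val, _ = quad(lambda h: -disjoining_pressure(h, hs, 1.0), hs, np.inf,
                  limit=200)
    assert val == pytest.approx(0.5, rel=1e-6)
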