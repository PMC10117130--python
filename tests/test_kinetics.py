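"""Rate laws, closed forms and the coupled ODE solution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssfkin.kinetics import (
    cpr_model,
    enzyme_rhs,
    hybrid_growth_rate,
    lignin_closed_form,
    lignin_decay_coeff,
    lignin_rate,
    logistic_closed_form,
    logistic_rhs,
    monod_mu,
    our_model,
    simulate_trajectory,
    substrate_rhs,
)
from ssfkin.params import InitialConditions, KineticParams


def kp(**kw):
    base = dict(mu_max=1.0, K_s=0.5, X_m=0.08, Y_XS=0.2)
    base.update(kw)
    return KineticParams(**base)


class TestMonod:
    def test_half_saturation_definition(self):
        p = kp(mu_max=1.21, K_s=0.664)
        assert monod_mu(p.K_s, p) == pytest.approx(0.5 * p.mu_max)

    @pytest.mark.parametrize(
        "S, expected",
        [(0.0, 0.0), (0.586, 1.210 * 0.586 / (0.664 + 0.586))],
    )
    def test_values(self, S, expected):
        p = kp(mu_max=1.210, K_s=0.664)
        assert monod_mu(S, p) == pytest.approx(expected, rel=1e-12)
        # hand value for the nonzero case
        if S:
            assert monod_mu(S, p) == pytest.approx(0.5672, abs=5e-5)

    def test_monotone_and_saturating(self):
        p = kp()
        S = np.linspace(0, 50, 200)
        mu = monod_mu(S, p)
        assert np.all(np.diff(mu) > 0)
        assert mu[-1] < p.mu_max
        assert monod_mu(1e9, p) == pytest.approx(p.mu_max, rel=1e-6)

    def test_negative_substrate_rejected(self):
        with pytest.raises(ValueError):
            monod_mu(-0.1, kp())


class TestHybridGrowth:
    def test_vanishes_at_capacity_and_empty(self):
        p = kp()
        assert hybrid_growth_rate(p.X_m, 0.5, p) == pytest.approx(0.0, abs=1e-15)
        assert hybrid_growth_rate(0.0, 0.5, p) == 0.0
        assert hybrid_growth_rate(0.04, 0.0, p) == 0.0

    def test_hand_value(self):
        p = kp(mu_max=1.0, K_s=0.5, X_m=0.08)
        # Monod factor 0.5, logistic factor 0.5, X=0.04
        assert hybrid_growth_rate(0.04, 0.5, p) == pytest.approx(0.01, rel=1e-12)

    def test_substrate_rich_limit_is_logistic(self):
        p = kp()
        X = 0.03
        assert hybrid_growth_rate(X, 1e9, p) == pytest.approx(
            logistic_rhs(X, p), rel=1e-8
        )


class TestLogistic:
    def test_identity_at_t0(self):
        p = kp()
        assert logistic_closed_form(0.0, 0.008, p) == pytest.approx(0.008)

    def test_half_capacity_time(self):
        p = kp(mu_max=1.0, X_m=0.08)
        assert logistic_closed_form(np.log(9.0), 0.008, p) == pytest.approx(
            0.04, rel=1e-12
        )

    def test_max_rate_at_half_capacity(self):
        p = kp()
        assert logistic_rhs(p.X_m / 2, p) == pytest.approx(p.mu_max * p.X_m / 4)

    def test_rejects_nonpositive_x0(self):
        with pytest.raises(ValueError):
            logistic_closed_form(1.0, 0.0, kp())


class TestLignin:
    def test_decay_coeff(self):
        p = kp(k1=0.008, k2=-0.043)
        assert lignin_decay_coeff(0.0, p) == p.k1
        assert lignin_decay_coeff(30.0, p) == pytest.approx(
            0.008 * np.exp(1.29), rel=1e-12
        )
        assert lignin_decay_coeff(30.0, p) == pytest.approx(0.02906, abs=5e-6)
        pz = kp(k1=0.008, k2=0.0)
        assert lignin_decay_coeff(17.0, pz) == pz.k1

    def test_closed_form_boundaries(self):
        p = kp(k1=0.008, k2=-0.043)
        assert lignin_closed_form(0.0, 0.373, p) == pytest.approx(0.373)
        p0 = kp(k1=0.0, k2=-0.043)
        assert lignin_closed_form(25.0, 0.373, p0) == pytest.approx(0.373)

    def test_k2_zero_branch_is_plain_exponential(self):
        p = kp(k1=0.01, k2=0.0)
        t = np.linspace(0, 30, 7)
        np.testing.assert_allclose(
            lignin_closed_form(t, 0.3, p), 0.3 * np.exp(-0.01 * t), rtol=1e-14
        )

    def test_closed_form_against_rk4_oracle(self):
        # independent fixed-step RK4 of dL/dt = -k1 e^{-k2 t} L
        p = kp(k1=0.008, k2=-0.043)
        L0, T, n = 0.373, 30.0, 30000
        h = T / n
        L, t = L0, 0.0
        f = lambda t, L: -p.k1 * np.exp(-p.k2 * t) * L
        for _ in range(n):
            q1 = f(t, L)
            q2 = f(t + h / 2, L + h / 2 * q1)
            q3 = f(t + h / 2, L + h / 2 * q2)
            q4 = f(t + h, L + h * q3)
            L += h / 6 * (q1 + 2 * q2 + 2 * q3 + q4)
            t += h
        assert L == pytest.approx(0.2285, abs=1e-4)
        assert lignin_closed_form(T, L0, p) == pytest.approx(L, rel=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(
        k1=st.floats(0.0, 0.02),
        k2=st.floats(-0.1, 0.1),
        t=st.floats(0.1, 30.0),
    )
    def test_rate_matches_finite_difference(self, k1, k2, t):
        p = kp(k1=k1, k2=k2)
        L0, h = 0.373, 1e-5
        fd = (lignin_closed_form(t + h, L0, p) - lignin_closed_form(t - h, L0, p)) / (2 * h)
        r = lignin_rate(t, L0, p)
        # abs floor covers the oracle's own cancellation error (~eps*L0/h)
        assert r == pytest.approx(fd, rel=1e-6, abs=5e-11)
        assert r <= 0.0

    def test_rate_boundaries(self):
        assert lignin_rate(5.0, 0.3, kp(k1=0.0, k2=-0.05)) == 0.0
        p = kp(k1=0.008, k2=-0.043)
        assert lignin_rate(0.0, 0.373, p) == pytest.approx(-p.k1 * 0.373)


class TestAlgebraicRates:
    def test_substrate_rhs_hand_value(self):
        # k_LD=0: dS/dt = -dX/dt / Y_XS - m_s X with dX/dt = 0.01
        p = kp(mu_max=1.0, K_s=0.5, X_m=0.08, Y_XS=0.2, m_s=0.08, k_LD=0.0)
        assert substrate_rhs(0.04, 0.5, 0.0, p) == pytest.approx(-0.0532, rel=1e-10)

    def test_substrate_rhs_vanishes_without_biomass_or_decay(self):
        p = kp(m_s=0.1, k_LD=0.5, k1=0.0)
        assert substrate_rhs(0.0, 0.5, 0.0, p) == 0.0

    def test_substrate_rhs_sign_conventions(self):
        p = kp(k_LD=0.5)
        dLdt = -0.01  # lignin being lost
        as_printed = substrate_rhs(0.0, 0.0, dLdt, p, "as_printed")
        energy = substrate_rhs(0.0, 0.0, dLdt, p, "energy_cost")
        assert as_printed == pytest.approx(+0.005)   # literal: adds substrate
        assert energy == pytest.approx(-0.005)       # energy cost: consumes
        with pytest.raises(ValueError):
            substrate_rhs(0.0, 0.0, dLdt, p, "bogus")

    @pytest.mark.parametrize(
        "fn, params, X, dXdt, expected",
        [
            (our_model, dict(Y_XO=1.0, m_O=20.0), 0.05, 0.0, 1.0),
            (our_model, dict(Y_XO=0.018, m_O=20.567), 0.05, 0.01, 1.5839),
            (our_model, dict(Y_XO=0.018, m_O=20.567), 0.0, 0.0, 0.0),
            (cpr_model, dict(Y_CX=1.0, m_C=17.0), 0.05, 0.0, 0.85),
            (cpr_model, dict(Y_CX=26.741, m_C=17.091), 0.05, 0.01, 1.1220),
            (enzyme_rhs, dict(alpha=0.15, beta=0.005), 0.05, 0.01, 0.00175),
            (enzyme_rhs, dict(alpha=0.15, beta=0.005), 0.0, 0.0, 0.0),
        ],
    )
    def test_gas_and_enzyme_rates(self, fn, params, X, dXdt, expected):
        p = kp(**params)
        assert fn(X, dXdt, p) == pytest.approx(expected, abs=5e-5)

    def test_stationary_enzyme_is_non_growth_associated(self):
        p = kp(alpha=0.15, beta=0.005)
        assert enzyme_rhs(0.05, 0.0, p) == pytest.approx(p.beta * 0.05)


class TestSimulateTrajectory:
    IC = InitialConditions(X0=0.005, S0=0.586, L0=0.373)

    def full_params(self):
        return KineticParams(
            mu_max=1.21, K_s=0.664, X_m=0.084, Y_XS=0.249, m_s=0.081,
            k_LD=0.787, k1=0.005, k2=-0.053, Y_XO=0.018, m_O=20.567,
            Y_CX=26.741, m_C=17.091, alpha=0.154, beta=0.005,
        )

    def test_zero_duration_grid_returns_ic(self):
        traj = simulate_trajectory(self.IC, self.full_params(), [0.0])
        assert traj.X[0] == self.IC.X0
        assert traj.S[0] == self.IC.S0
        assert traj.L[0] == self.IC.L0
        assert traj.cum_O2[0] == 0.0

    def test_grid_validation(self):
        p = self.full_params()
        with pytest.raises(ValueError):
            simulate_trajectory(self.IC, p, [0.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            simulate_trajectory(self.IC, p, [1.0, 2.0])
        with pytest.raises(ValueError):
            bad_ic = InitialConditions(X0=0.09, S0=0.586, L0=0.373)
            simulate_trajectory(bad_ic, p, [0.0, 1.0])

    def test_substrate_rich_limit_matches_logistic(self):
        p = self.full_params().replace(K_s=1e-9, m_s=0.0, k_LD=0.0)
        t = np.linspace(0, 14, 15)
        traj = simulate_trajectory(self.IC, p, t)
        np.testing.assert_allclose(
            traj.X, logistic_closed_form(t, self.IC.X0, p), rtol=1e-4
        )

    def test_lignin_channel_matches_closed_form(self):
        p = self.full_params()
        t = np.linspace(0, 30, 16)
        traj = simulate_trajectory(self.IC, p, t)
        np.testing.assert_allclose(
            traj.L, lignin_closed_form(t, self.IC.L0, p), rtol=1e-7
        )

    def test_monotonicity_and_capacity(self):
        traj = simulate_trajectory(self.IC, self.full_params(), np.arange(31.0))
        assert np.all(np.diff(traj.X) >= -1e-12)
        assert np.all(np.diff(traj.L) <= 1e-12)
        assert np.all(traj.X <= self.full_params().X_m * (1 + 1e-7))
        assert np.all(traj.X >= 0) and np.all(traj.S >= 0)

    @settings(max_examples=10, deadline=None)
    @given(
        mu=st.floats(0.3, 1.5),
        Ks=st.floats(0.1, 1.0),
        Xm=st.floats(0.03, 0.12),
    )
    def test_capacity_never_crossed(self, mu, Ks, Xm):
        p = KineticParams(mu_max=mu, K_s=Ks, X_m=Xm, Y_XS=0.25)
        traj = simulate_trajectory(self.IC, p, np.arange(0.0, 31.0, 3.0))
        assert traj.X.max() <= Xm * (1 + 1e-7)

    def test_substrate_balance_consistency(self):
        """Differenced S matches the three Eq.-style sinks within tolerance."""
        p = self.full_params()
        t = np.arange(0.0, 30.001, 0.25)
        traj = simulate_trajectory(self.IC, p, t)
        dS = np.gradient(traj.S, t)
        dX = np.gradient(traj.X, t)
        dL = np.gradient(traj.L, t)
        rhs = -dX / p.Y_XS - p.m_s * traj.X - p.k_LD * dL
        # central differences carry O(h^2) error; compare away from endpoints
        np.testing.assert_allclose(dS[2:-2], rhs[2:-2], atol=2e-4)

    def test_grid_refinement_invariance(self):
        p = self.full_params()
        coarse = simulate_trajectory(self.IC, p, np.arange(0.0, 31.0, 2.0))
        fine = simulate_trajectory(self.IC, p, np.arange(0.0, 31.0, 1.0))
        np.testing.assert_allclose(coarse.OUR, fine.OUR[::2], rtol=1e-5)
        np.testing.assert_allclose(coarse.CPR, fine.CPR[::2], rtol=1e-5)
        np.testing.assert_allclose(coarse.X, fine.X[::2], rtol=1e-6)
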