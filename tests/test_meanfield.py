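"""Mean-field right-hand sides, integration, and the multi-population system."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qifex.geometry import CriticalManifold
from qifex.meanfield import (
    Trajectory,
    extended_rhs,
    integrate_trajectory,
    make_rhs,
    multipop_rhs,
)
from qifex.params import (
    MeanFieldParams,
    MultiPopParams,
    SlowForcing,
    effective_coefficients,
)


class TestEffectiveCoefficients:
    @pytest.mark.parametrize(
        "gamma,g,a,expect",
        [
            (0.0, 0.0, 1.0, (0.0, 0.0)),  # all extensions off
            (math.pi, 0.0, 1.0, (1.0, 0.0)),
            (0.0, 2.0, 1.0, (-2.0, 0.0)),  # ln 1 = 0
            (math.pi, 0.5, math.e, (1.0 - 0.5, 0.5)),
        ],
    )
    def test_closed_forms(self, gamma, g, a, expect):
        gt, off = effective_coefficients(gamma, g, a)
        assert gt == pytest.approx(expect[0])
        assert off == pytest.approx(expect[1])

    def test_nonpositive_spike_asymmetry_rejected(self):
        with pytest.raises(ValueError):
            effective_coefficients(0.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            MeanFieldParams(a_spike=-1.0)


class TestExtendedRhs:
    def test_direct_substitution_at_origin(self):
        p = MeanFieldParams(delta=1.0, j_syn=15.0, eta_bar=-2.0, tau_s=0.1)
        eps = 0.05
        d = extended_rhs((0.0, 0.0, 0.0, p.eta_bar, 0.0), p, eps)
        # slow time: eps*r' = Delta/pi -> r' = Delta/(pi eps); v' = eta_bar/eps
        assert d[0] == pytest.approx(1.0 / (math.pi * eps))
        assert d[1] == pytest.approx(p.eta_bar / eps)
        assert d[2] == 0.0 and d[3] == 0.0 and d[4] == 0.0

    def test_fast_and_slow_forms_are_proportional(self):
        p = MeanFieldParams(delta=1.0, j_syn=15.0, eta_bar=-5.0, tau_s=0.02)
        eps = 0.05
        y = (0.3, -1.2, 0.25, -4.0, 2.0)
        slow = extended_rhs(y, p, eps, time_scale="slow")
        fast = extended_rhs(y, p, eps, time_scale="fast")
        np.testing.assert_allclose(fast[:3], slow[:3] * eps, rtol=1e-14)
        np.testing.assert_allclose(fast[3:], slow[3:] * eps, rtol=1e-14)

    def test_equilibrium_branch_zeroes_fast_rhs(self):
        """Cross-module oracle: (r(v), v, r(v), K=-psi(v)) is an exact
        equilibrium of the fast subsystem for 50 voltages."""
        p = MeanFieldParams(delta=1.0, j_syn=15.0, eta_bar=-15.1, tau_s=0.002)
        man = CriticalManifold(p)
        for v in np.linspace(-8.0, -0.05, 50):
            r = float(man.rate(v))
            d = extended_rhs((r, v, r, -float(man.psi(v)), 0.0), p, 0.05,
                             time_scale="fast")
            assert np.abs(d[:3]).max() < 1e-10

    def test_harmonic_invariant_of_forcing_oscillator(self):
        p = MeanFieldParams(eta_bar=-3.0)
        y = (0.1, -1.0, 0.1, -2.0, 4.0)
        d = extended_rhs(y, p, 0.1, time_scale="fast")
        K, Q = y[3], y[4]
        # d/dt[(K-eta_bar)^2 + Q^2] = 2(K-eta_bar)K' + 2QQ' = 0
        assert (K - p.eta_bar) * d[3] + Q * d[4] == pytest.approx(0.0, abs=1e-14)

    def test_invalid_epsilon_rejected(self):
        with pytest.raises(ValueError):
            extended_rhs((0, 0, 0, 0, 0), MeanFieldParams(), 0.0)


class TestIntegration:
    def test_forcing_subsystem_matches_closed_form(self):
        """(K, Q) alone solve K(t) = eta_bar + A sin(eps t).

        Delta = J = 0 and K < 0 throughout keep (r, v) pinned on the rest
        branch so the harmonic pair is exercised in isolation.
        """
        p = MeanFieldParams(delta=0.0, j_syn=0.0, eta_bar=-1.5, tau_s=1.0)
        eps, A = 0.05, 1.0
        t_eval = np.linspace(0, 2 * math.pi / eps, 200)
        traj = integrate_trajectory(
            make_rhs(p, eps, "fast"),
            (0.0, -math.sqrt(1.5), 0.0, p.eta_bar, A),
            (0.0, t_eval[-1]),
            t_eval=t_eval,
            rtol=1e-10,
            atol=1e-12,
        )
        np.testing.assert_allclose(
            traj.K, p.eta_bar + A * np.sin(eps * traj.times), rtol=1e-8, atol=1e-8
        )
        inv = (traj.K - p.eta_bar) ** 2 + traj.Q**2
        np.testing.assert_allclose(inv, A**2, rtol=1e-8)

    def test_synapse_relaxes_to_frozen_rate(self):
        """With r frozen at c the synapse converges as c + (s0-c)e^(-t/tau)."""
        tau = 0.3
        c, s0 = 0.7, 0.1
        rhs = lambda t, y: [(-y[0] + c) / tau]
        from scipy.integrate import solve_ivp

        sol = solve_ivp(rhs, (0, 3.0), [s0], rtol=1e-10, atol=1e-12,
                        t_eval=np.linspace(0, 3, 50))
        expect = c + (s0 - c) * np.exp(-sol.t / tau)
        np.testing.assert_allclose(sol.y[0], expect, rtol=1e-7)

    def test_unforced_run_converges_to_manifold_equilibrium(self, mpr_params):
        """With A = 0 the mean field settles onto S0: fast RHS residual ~ 0."""
        p = mpr_params
        man = CriticalManifold(p)
        v0 = man.branch_voltage(p.eta_bar, "lower")
        y0 = (float(man.rate(v0)) * 1.3, v0 * 1.05, float(man.rate(v0)), p.eta_bar, 0.0)
        traj = integrate_trajectory(
            make_rhs(p, 0.05, "fast"), y0, (0.0, 40.0), rtol=1e-10, atol=1e-12
        )
        end = traj.states[-1]
        resid = extended_rhs(end, p, 0.05, time_scale="fast")[:3]
        assert np.abs(resid).max() < 1e-8

    def test_rate_stays_positive(self, mpr_params):
        traj = integrate_trajectory(
            make_rhs(mpr_params, 0.05, "fast"),
            (0.01, -4.0, 0.01, mpr_params.eta_bar, 5.0),
            (0.0, 60.0),
            t_eval=np.linspace(0, 60, 500),
        )
        assert (traj.r > 0).all()

    def test_trajectory_validation(self):
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 0.0, 1.0]), np.zeros((3, 5)))
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 1.0]), np.zeros((3, 5)))


class TestMultiPop:
    def _pack(self, triples, K, Q):
        return np.concatenate([np.ravel(triples), [K, Q]])

    @given(
        st.lists(st.floats(-2, 2), min_size=3, max_size=3),
        st.floats(-20, 5),
        st.floats(-5, 5),
    )
    @settings(max_examples=30, deadline=None)
    def test_single_population_reduces_to_extended_rhs(self, triple, K, Q):
        p = MeanFieldParams(delta=1.0, j_syn=15.0, eta_bar=-15.1, tau_s=0.02)
        mp = MultiPopParams(
            populations=(p,), coupling=((p.j_tilde,),), forced_index=0,
            forcing=SlowForcing(1.0, 0.05),
        )
        r, v, s = triple
        y = self._pack([(r, v, s)], K, Q)
        got = multipop_rhs(y, mp, 0.05)
        want = extended_rhs((r, v, s, K, Q), p, 0.05)
        np.testing.assert_allclose(got, want, rtol=1e-14, atol=1e-14)

    def test_symmetric_pair_has_identical_derivatives(self):
        p = MeanFieldParams(delta=1.0, j_syn=10.0, eta_bar=-4.0, tau_s=0.05)
        mp = MultiPopParams(
            populations=(p, p),
            coupling=((5.0, 2.0), (2.0, 5.0)),
            forced_index=0,
        )
        # forcing applied to population 0 only, but with K = eta_bar the
        # forced drive equals the unforced baseline -> symmetric states
        y = self._pack([(0.2, -1.0, 0.2), (0.2, -1.0, 0.2)], p.eta_bar, 0.0)
        d = multipop_rhs(y, mp, 0.05)
        np.testing.assert_allclose(d[0:3], d[3:6], rtol=1e-14)

    def test_decoupled_pair_matches_standalone(self):
        pa = MeanFieldParams(delta=1.0, j_syn=15.0, eta_bar=-15.1, tau_s=0.02)
        pb = MeanFieldParams(delta=0.5, j_syn=8.0, eta_bar=-3.0, tau_s=0.1)
        mp = MultiPopParams(
            populations=(pa, pb),
            coupling=((pa.j_tilde, 0.0), (0.0, pb.j_tilde)),
            forced_index=0,
        )
        ya = (0.3, -2.0, 0.25)
        yb = (0.1, -1.0, 0.15)
        K, Q = -14.0, 3.0
        d = multipop_rhs(self._pack([ya, yb], K, Q), mp, 0.05)
        da = extended_rhs((*ya, K, Q), pa, 0.05)
        np.testing.assert_allclose(d[0:3], da[:3], rtol=1e-14)
        # unforced population keeps its own eta_bar and sees no K
        db = extended_rhs((*yb, pb.eta_bar, 0.0), pb, 0.05)
        np.testing.assert_allclose(d[3:6], db[:3], rtol=1e-14)

    def test_dimension_mismatch_rejected(self):
        p = MeanFieldParams()
        mp = MultiPopParams(populations=(p, p), coupling=((0, 0), (0, 0)))
        with pytest.raises(ValueError):
            multipop_rhs(np.zeros(6), mp, 0.05)
        with pytest.raises(ValueError):
            MultiPopParams(populations=(p, p), coupling=((0.0,),))
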