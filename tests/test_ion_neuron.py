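"""Unit and property tests for the single-cell ion-concentration model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurocosim.ion_neuron import (ClassifierConfig, FiringPattern,
                                   IonNeuronParams, IonNeuronState,
                                   classify_pattern, concentrations,
                                   conductances, derivatives, detect_spikes,
                                   gating_steady, h_of_n, integrate, nernst,
                                   pump_current, resting_state)


class TestNernst:
    def test_equal_concentrations_zero(self):
        assert nernst(5.0, 5.0, 26.64, 1) == 0.0

    def test_e_fold_ratio_gives_prefactor(self):
        assert nernst(5.0 * math.e, 5.0, 26.64, 1) == pytest.approx(26.64)

    def test_negative_valence_flips_sign(self):
        assert nernst(10.0, 5.0, 26.64, -1) == -nernst(10.0, 5.0, 26.64, 1)

    @pytest.mark.parametrize("out,inn", [(0.0, 5.0), (5.0, 0.0),
                                         (-1.0, 5.0)])
    def test_nonpositive_concentration_rejected(self, out, inn):
        with pytest.raises(ValueError):
            nernst(out, inn, 26.64, 1)


class TestPump:
    def test_half_activation_point(self, default_params):
        # both exponent arguments vanish at Na_i=21, K_o=5.5
        expected = default_params.rho / 4.0
        assert pump_current(default_params, 21.0, 5.5) == \
            pytest.approx(expected)

    def test_saturation_limit(self, default_params):
        assert pump_current(default_params, 1e3, 1e3) == \
            pytest.approx(default_params.rho)

    def test_deep_deactivation(self, default_params):
        val = pump_current(default_params, 0.0, 0.0)
        expected = default_params.rho / ((1 + math.exp(10.5)) *
                                         (1 + math.exp(5.5)))
        assert val == pytest.approx(expected, rel=1e-12)

    @given(st.floats(-50, 100), st.floats(-10, 60))
    @settings(max_examples=50, deadline=None)
    def test_bounded_in_zero_rho(self, na_i, k_o):
        p = IonNeuronParams()
        val = pump_current(p, na_i, k_o)
        assert 0.0 < val <= p.rho


class TestGating:
    def test_n_half_activation(self):
        n_inf, _ = gating_steady(-19.0)
        assert n_inf == pytest.approx(0.5)

    def test_m_half_activation(self):
        # exp(-(2 + V/12)) has zero argument at V = -24
        _, m_inf = gating_steady(-24.0)
        assert m_inf == pytest.approx(0.5)

    def test_n_direct_value(self):
        n_inf, _ = gating_steady(-1.0)
        assert n_inf == pytest.approx(1 / (1 + math.exp(-1)), rel=1e-12)

    @given(st.floats(-200, 200))
    @settings(max_examples=100, deadline=None)
    def test_strictly_in_unit_interval(self, v):
        n_inf, m_inf = gating_steady(v)
        assert 0.0 < n_inf < 1.0
        assert 0.0 < m_inf < 1.0


class TestHofN:
    def test_midpoint(self):
        assert h_of_n(0.4) == pytest.approx(0.6)

    def test_large_n_limit(self):
        assert h_of_n(100.0) == pytest.approx(0.1, abs=1e-6)

    def test_at_zero(self):
        assert h_of_n(0.0) == pytest.approx(1.1 - 1 / (1 + math.exp(3.2)),
                                            rel=1e-12)


class TestConductances:
    def test_zero_gate_zero_leak(self):
        p = IonNeuronParams(gl_K=0.0)
        gk, _, _ = conductances(p, 0.0, -60.0)
        assert gk == 0.0

    def test_na_collapses_to_leak(self):
        p = IonNeuronParams(g0_Na=0.0)
        for v, n in [(-70, 0.1), (0, 0.9)]:
            assert conductances(p, n, v)[1] == p.gl_Na

    def test_chloride_state_independent(self, default_params):
        g1 = conductances(default_params, 0.1, -70.0)[2]
        g2 = conductances(default_params, 0.9, 10.0)[2]
        assert g1 == g2 == default_params.g0_Cl


class TestConcentrations:
    def test_baselines_at_zero(self, default_params):
        p = default_params
        assert concentrations(p, 0.0, 0.0) == (p.K0_i, p.K0_o, p.Na0_i,
                                               p.Na0_o, p.Cl0_i, p.Cl0_o)

    @given(st.floats(-10, 10), st.floats(-10, 50))
    @settings(max_examples=100, deadline=None)
    def test_bookkeeping_identities(self, dki, kg):
        p = IonNeuronParams()
        k_i, k_o, na_i, na_o, cl_i, cl_o = concentrations(p, dki, kg)
        assert na_i + dki == pytest.approx(p.Na0_i, abs=1e-12)
        assert k_i - dki == pytest.approx(p.K0_i, abs=1e-12)
        assert k_o + p.beta_vol * dki - kg == pytest.approx(p.K0_o,
                                                           abs=1e-9)
        assert na_o - p.beta_vol * dki == pytest.approx(p.Na0_o, abs=1e-9)
        assert (cl_i, cl_o) == (p.Cl0_i, p.Cl0_o)


class TestDerivatives:
    def test_gamma_zero_freezes_potassium(self, default_params, rest):
        from dataclasses import replace

        p = replace(default_params, gamma_flux=0.0)
        d = derivatives(p, rest)
        assert d[2] == 0.0

    def test_epsilon_zero_freezes_bath(self, default_params, rest):
        from dataclasses import replace

        p = replace(default_params, epsilon=0.0)
        d = derivatives(p, rest)
        assert d[3] == 0.0

    def test_fixed_point_from_root_oracle(self, default_params):
        """At a numerically located equilibrium all derivatives vanish."""
        from scipy.optimize import least_squares

        p = default_params.with_kbath(4.0)

        scale = np.array([1.0, 1e2, 1e5, 1e4])  # balance stiff components

        def rhs(y):
            try:
                return scale * derivatives(
                    p, IonNeuronState(V=y[0], n=y[1], DeltaK_i=y[2],
                                      K_g=y[3]))
            except FloatingPointError:
                return np.full(4, 1e6)  # infeasible concentrations

        s = resting_state(p)
        sol = least_squares(
            rhs, [s.V, s.n, 0.0, 0.0],
            bounds=([-120.0, 1e-6, -4.0, -40.0], [20.0, 1.0, 14.0, 30.0]),
            xtol=3e-16, ftol=3e-16, gtol=3e-16)
        d = rhs(sol.x) / scale
        assert np.max(np.abs(d)) < 1e-8


class TestIntegrate:
    def test_zero_duration_returns_initial(self, default_params, rest):
        tr = integrate(default_params, rest, 0.0)
        assert tr.V.shape[0] == 1
        assert tr.V[0, 0] == rest.V

    def test_dt_convergence(self, quiescent):
        # subthreshold segment: fully adapted silent cell, perturbed
        p, eq = quiescent
        s0 = IonNeuronState(V=eq.V + 8.0, n=eq.n, DeltaK_i=eq.DeltaK_i,
                            K_g=eq.K_g)
        v_ref = integrate(p, s0, 1000.0, dt=0.0125).V[-1, 0]
        v_half = integrate(p, s0, 1000.0, dt=0.025).V[-1, 0]
        v_full = integrate(p, s0, 1000.0, dt=0.05).V[-1, 0]
        assert abs(v_half - v_ref) <= abs(v_full - v_ref) + 1e-6
        assert abs(v_full - v_ref) < 2.0  # mV on a subthreshold segment

    def test_fast_subsystem_matches_generic_ode_solver(self):
        """With frozen ion concentrations the 2-variable (V, n) subsystem
        must agree with an independent adaptive integrator."""
        from scipy.integrate import solve_ivp

        from dataclasses import replace

        from neurocosim.ion_neuron import integrate as _integrate

        base = IonNeuronParams(K_bath=2.5)
        eq = _integrate(base, resting_state(base), 30_000.0, dt=0.05,
                        sample_every=600_000)
        p = replace(base, gamma_flux=0.0, epsilon=0.0)
        # perturbed quiescent clamp: a decaying transient, no spikes
        s0 = IonNeuronState(V=float(eq.V[-1, 0]) + 5.0,
                            n=float(eq.n[-1, 0]),
                            DeltaK_i=float(eq.DeltaK_i[-1, 0]),
                            K_g=float(eq.K_g[-1, 0]))

        def rhs(t, y):
            s = IonNeuronState(V=y[0], n=y[1], DeltaK_i=s0.DeltaK_i,
                               K_g=s0.K_g)
            d = derivatives(p, s)
            return [d[0], d[1]]

        sol = solve_ivp(rhs, (0, 200.0), [s0.V, s0.n],
                        rtol=1e-10, atol=1e-12, dense_output=True)
        tr = integrate(p, s0, 200.0, dt=0.002, sample_every=1000)
        for tk, vk in zip(tr.t, tr.V[:, 0]):
            v_ref = sol.sol(tk)[0]
            assert vk == pytest.approx(v_ref, rel=1e-4, abs=1e-3)

    def test_deterministic(self, default_params, rest):
        t1 = integrate(default_params.with_kbath(9.5), rest, 500.0)
        t2 = integrate(default_params.with_kbath(9.5), rest, 500.0)
        assert np.array_equal(t1.V, t2.V)


class TestDetectSpikes:
    def test_constant_below_threshold(self):
        assert detect_spikes(np.full(100, -70.0)).size == 0

    def test_single_crossing_interpolated(self):
        v = np.array([-10.0, -10.0, 10.0, 10.0])
        t = detect_spikes(v, threshold=0.0, dt=1.0)
        assert t.shape == (1,)
        assert t[0] == pytest.approx(1.5)

    @pytest.mark.parametrize("freq", [3.0, 7.0])
    def test_sinusoid_counting_oracle(self, freq):
        dur = 2.0  # s
        dt = 0.1  # ms
        t = np.arange(0, dur * 1000, dt)
        v = 20.0 * np.sin(2 * np.pi * freq * t / 1000.0) - 5.0
        spikes = detect_spikes(v, threshold=0.0, dt=dt)
        assert spikes.size == round(freq * dur)


class TestClassifier:
    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            classify_pattern(np.empty(0), np.empty(0))

    def test_flat_hyperpolarized_is_rs(self):
        v = np.full(1000, -65.0)
        assert classify_pattern(v, np.empty(0)) is FiringPattern.RS

    def test_flat_depolarized_is_db(self):
        v = np.full(1000, -25.0)
        assert classify_pattern(v, np.empty(0)) is FiringPattern.DB

    def test_regular_train_is_ts(self):
        t = np.arange(0, 10_000.0)
        v = np.full(t.size, -60.0)
        spikes = np.arange(50.0, 10_000.0, 100.0)
        assert classify_pattern(v, spikes, t=t) is FiringPattern.TS

    def test_early_terminating_train_is_st(self):
        t = np.arange(0, 10_000.0)
        v = np.full(t.size, -60.0)
        spikes = np.arange(2600.0, 5000.0, 100.0)
        assert classify_pattern(v, spikes, t=t) is FiringPattern.ST

    def test_short_clustered_events_are_burst(self):
        t = np.arange(0, 20_000.0)
        v = np.full(t.size, -60.0)
        spikes = np.concatenate([
            np.arange(s, s + 400.0, 20.0)
            for s in np.arange(5000.0, 19_500.0, 1600.0)])
        assert classify_pattern(v, spikes, t=t) is FiringPattern.BURST

    def test_long_separated_events_are_sle(self):
        t = np.arange(0, 30_000.0)
        v = np.full(t.size, -60.0)
        spikes = np.concatenate([
            np.arange(s, s + 3000.0, 25.0)
            for s in [8000.0, 10_000.0 + 3000.0, 16_000.0 + 4000.0,
                      26_000.0]])
        assert classify_pattern(v, spikes, t=t) is FiringPattern.SLE


def test_low_bath_settles_to_rest(default_params):
    """At K_bath = 4 mM the cell is silent once the bath equilibrates."""
    p = default_params.with_kbath(4.0)
    s = resting_state(p)
    tr = integrate(p, s, 14_000.0, dt=0.05)
    late = tr.spikes[0][tr.spikes[0] > 8000.0]
    assert late.size == 0
    assert tr.V[-1, 0] < -55.0


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        IonNeuronParams(K_bath=-1.0)
    with pytest.raises(ValueError):
        IonNeuronParams(g0_K=-0.5)
    with pytest.raises(ValueError):
        IonNeuronParams(beta_vol=0.0)
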