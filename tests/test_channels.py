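"""Rate laws, gates, kinetic schemes, Q10, calcium pools."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nml1 import channels as ch


def k_gate():
    """Classic squid delayed-rectifier n gate."""
    return ch.Gate(
        "n", instances=4,
        forward=ch.RateLaw("exp_linear", rate=0.1, scale=0.1,
                           midpoint=-55.0),
        backward=ch.RateLaw("exponential", rate=0.125, scale=-1.0 / 80.0,
                            midpoint=-65.0))


class TestRateLaws:
    def test_exponential_at_midpoint_equals_rate(self):
        law = ch.RateLaw("exponential", rate=2.5, scale=0.2, midpoint=-30.0)
        assert ch.evaluate_rate(law, -30.0) == pytest.approx(2.5)

    def test_sigmoid_at_midpoint_is_half_rate(self):
        law = ch.RateLaw("sigmoid", rate=2.0, scale=-0.1, midpoint=-35.0)
        assert ch.evaluate_rate(law, -35.0) == pytest.approx(1.0)

    def test_exp_linear_limit_at_midpoint(self):
        law = ch.RateLaw("exp_linear", rate=0.1, scale=0.1, midpoint=-55.0)
        assert ch.evaluate_rate(law, -55.0) == pytest.approx(0.1)
        # continuity through the guard band
        near = ch.evaluate_rate(law, -55.0 + 1e-6)
        assert near == pytest.approx(0.1, rel=1e-5)

    def test_exp_linear_matches_closed_form_away_from_midpoint(self):
        law = ch.RateLaw("exp_linear", rate=0.1, scale=0.1, midpoint=-55.0)
        v = -40.0
        x = 0.1 * (v + 55.0)
        assert ch.evaluate_rate(law, v) == \
            pytest.approx(0.1 * x / (1 - math.exp(-x)), rel=1e-12)

    def test_generic_expression_matches_sigmoid(self):
        gen = ch.RateLaw("generic",
                         expression="2.0/(1 + exp(-0.1*(v + 35)))")
        ref = ch.RateLaw("sigmoid", rate=2.0, scale=-0.1, midpoint=-35.0)
        grid = np.linspace(-100, 60, 161)
        np.testing.assert_allclose(ch.evaluate_rate(gen, grid),
                                   ch.evaluate_rate(ref, grid), rtol=1e-12)

    def test_negative_rate_raises_domain_error(self):
        law = ch.RateLaw("generic", expression="v")   # negative for v<0
        with pytest.raises(ch.DomainError):
            ch.evaluate_rate(law, -10.0)

    def test_fast_closure_agrees_with_checked_path(self):
        for law in (ch.RateLaw("exponential", 1.3, -0.04, -60.0),
                    ch.RateLaw("sigmoid", 0.9, 0.08, -20.0),
                    ch.RateLaw("exp_linear", 0.2, 0.12, -45.0)):
            fn = ch.rate_function(law)
            grid = np.linspace(-90, 50, 57)
            np.testing.assert_allclose(fn(grid),
                                       ch.evaluate_rate(law, grid),
                                       rtol=1e-12)


class TestQ10:
    def test_factor_three_scales_by_three_per_ten_degrees(self):
        q10 = ch.Q10Settings(q10_factor=3.0, experimental_temp=20.0)
        law = ch.RateLaw("exponential", rate=1.0, scale=0.0, midpoint=0.0)
        assert ch.evaluate_rate(law, 0.0, temp=30.0, q10=q10) == \
            pytest.approx(3.0)
        assert ch.evaluate_rate(law, 0.0, temp=10.0, q10=q10) == \
            pytest.approx(1.0 / 3.0)

    def test_identity_at_experimental_temperature(self):
        q10 = ch.Q10Settings(q10_factor=3.0, experimental_temp=22.0)
        assert q10.factor(22.0) == 1.0


class TestTauInf:
    def test_equal_rates_give_half_activation(self):
        g = ch.Gate("g", 1,
                    forward=ch.RateLaw("exponential", 0.4, 0.0, 0.0),
                    backward=ch.RateLaw("exponential", 0.4, 0.0, 0.0))
        tau, inf = ch.tau_inf(g, -10.0)
        assert inf == pytest.approx(0.5)
        assert tau == pytest.approx(1.0 / 0.8)

    def test_zero_backward_rate(self):
        g = ch.Gate("g", 1,
                    forward=ch.RateLaw("exponential", 2.0, 0.0, 0.0),
                    backward=ch.RateLaw("generic", expression="0"))
        tau, inf = ch.tau_inf(g, 0.0)
        assert inf == pytest.approx(1.0)
        assert tau == pytest.approx(0.5)

    def test_inf_monotone_when_alpha_rises_and_beta_falls(self):
        """Dense 1 mV grid oracle: with alpha increasing and beta
        decreasing in v, the steady state must increase monotonically."""
        grid = np.arange(-100.0, 60.0, 1.0)
        tau, inf = ch.tau_inf(k_gate(), grid)
        alpha = ch.evaluate_rate(k_gate().forward, grid)
        beta = ch.evaluate_rate(k_gate().backward, grid)
        assert np.all(np.diff(alpha) > 0) and np.all(np.diff(beta) < 0)
        assert np.all(np.diff(inf) > 0)
        np.testing.assert_allclose(inf, alpha / (alpha + beta), rtol=1e-12)

    def test_degenerate_point_raises(self):
        g = ch.Gate("g", 1,
                    forward=ch.RateLaw("generic", expression="0"),
                    backward=ch.RateLaw("generic", expression="0"))
        with pytest.raises(ch.DomainError):
            ch.tau_inf(g, 0.0)


class TestGateDynamics:
    def test_derivative_vanishes_at_steady_state(self):
        g = k_gate()
        _, inf = ch.tau_inf(g, -20.0)
        assert ch.gate_derivative(g, inf, -20.0) == pytest.approx(0.0,
                                                                  abs=1e-14)

    def test_derivative_from_zero_is_alpha(self):
        g = k_gate()
        alpha = ch.evaluate_rate(g.forward, -20.0)
        assert ch.gate_derivative(g, 0.0, -20.0) == pytest.approx(alpha)

    def test_relaxation_matches_closed_form(self):
        """m(t) = inf + (m0 - inf) exp(-t/tau) at constant voltage;
        oracle = fine-step explicit Euler integration."""
        g = k_gate()
        v, m0, t_end = -30.0, 0.1, 5.0
        tau, inf = ch.tau_inf(g, v)
        # explicit integration at dt = 1e-4 ms
        dt, m = 1e-4, m0
        for _ in range(int(t_end / dt)):
            m += dt * ch.gate_derivative(g, m, v)
        closed = inf + (m0 - inf) * math.exp(-t_end / tau)
        # explicit Euler at this dt carries O(dt) error of a few 1e-6
        assert m == pytest.approx(closed, abs=1e-5)


class TestChannelCurrent:
    def channel(self):
        return ch.ChannelType(id="k", max_conductance_density=36.0,
                              reversal_potential=-77.0, gates=[k_gate()])

    def test_zero_at_reversal_potential(self):
        assert ch.channel_current(self.channel(), [0.7], -77.0, 1000.0) == 0.0

    def test_fully_open_gives_max_conductance_times_driving_force(self):
        area = 1000.0
        i = ch.channel_current(self.channel(), [1.0], -27.0, area)
        assert i == pytest.approx(36.0 * area * 1e-5 * 50.0)

    def test_four_instances_at_half_give_a_sixteenth(self):
        # 0.5^4 = 0.0625 by hand
        area = 1000.0
        i = ch.channel_current(self.channel(), [0.5], -27.0, area)
        assert i == pytest.approx(36.0 * area * 1e-5 * 0.0625 * 50.0)

    def test_state_count_mismatch_raises(self):
        with pytest.raises(ch.ChannelError):
            ch.channel_current(self.channel(), [0.5, 0.5], 0.0, 1.0)


class TestKineticScheme:
    def test_two_state_scheme_equals_hh_gate(self):
        """The HH gate is the two-state special case: both integrations
        must produce the same trajectory."""
        g = k_gate()
        scheme = ch.hh_gate_as_scheme(g)
        v, dt = -40.0, 0.01
        occ = np.array([1.0, 0.0])
        m = 0.0
        tau, inf = ch.tau_inf(g, v)
        for _ in range(500):
            occ = ch.scheme_step(scheme, occ, v, dt)
            m = inf + (m - inf) * math.exp(-dt / tau)
        assert occ[1] == pytest.approx(m, abs=1e-9)
        assert scheme.open_fraction(occ) == pytest.approx(m, abs=1e-9)

    def test_all_rates_zero_leaves_occupancies_unchanged(self):
        scheme = ch.KineticScheme(
            states=[ch.SchemeState("a"), ch.SchemeState("b", open=True)],
            transitions=[])
        occ = ch.scheme_step(scheme, [0.3, 0.7], -50.0, 1.0)
        np.testing.assert_allclose(occ, [0.3, 0.7], atol=1e-15)

    def test_symmetric_three_cycle_equilibrates_to_one_third(self):
        const = ch.RateLaw("exponential", rate=1.0, scale=0.0, midpoint=0.0)
        scheme = ch.KineticScheme(
            states=[ch.SchemeState(s) for s in "abc"],
            transitions=[ch.SchemeTransition(a, b, const)
                         for a, b in [("a", "b"), ("b", "c"), ("c", "a"),
                                      ("b", "a"), ("c", "b"), ("a", "c")]])
        occ = np.array([1.0, 0.0, 0.0])
        for _ in range(200):
            occ = ch.scheme_step(scheme, occ, 0.0, 0.1)
        np.testing.assert_allclose(occ, [1 / 3] * 3, atol=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(rates=st.lists(st.floats(min_value=0.0, max_value=5.0),
                          min_size=6, max_size=6),
           occ0=st.lists(st.floats(min_value=0.01, max_value=1.0),
                         min_size=3, max_size=3),
           dt=st.floats(min_value=1e-3, max_value=10.0))
    def test_occupancies_stay_a_probability_vector(self, rates, occ0, dt):
        laws = [ch.RateLaw("exponential", rate=r, scale=0.0, midpoint=0.0)
                for r in rates]
        scheme = ch.KineticScheme(
            states=[ch.SchemeState(s, open=(s == "c")) for s in "abc"],
            transitions=[ch.SchemeTransition(a, b, law)
                         for (a, b), law in zip(
                             [("a", "b"), ("b", "c"), ("c", "a"),
                              ("b", "a"), ("c", "b"), ("a", "c")], laws)])
        occ = np.array(occ0) / sum(occ0)
        for _ in range(5):
            occ = ch.scheme_step(scheme, occ, -20.0, dt)
            assert abs(occ.sum() - 1.0) < 1e-12
            assert np.all(occ >= 0.0) and np.all(occ <= 1.0)


class TestCalciumPool:
    def pool(self):
        return ch.IonConcentrationModel(id="ca", resting_concentration=5e-5,
                                        decay_time_constant=20.0,
                                        influx_scaling=1e-4)

    def test_derivative_zero_at_rest_without_influx(self):
        assert ch.ca_pool_derivative(self.pool(), 5e-5, 0.0) == 0.0

    def test_free_decay_matches_analytic_exponential(self):
        pool = self.pool()
        c0, t = 1e-3, 13.0
        c = c0
        dt = 0.05
        for _ in range(int(t / dt)):
            c = ch.ca_pool_step(pool, c, 0.0, dt)
        analytic = pool.resting_concentration + \
            (c0 - pool.resting_concentration) * math.exp(-t / 20.0)
        assert c == pytest.approx(analytic, rel=1e-12)

    def test_constant_influx_steady_state(self):
        pool = self.pool()
        i_ca = 0.5
        target = pool.resting_concentration + 1e-4 * 20.0 * i_ca
        assert ch.ca_pool_derivative(pool, target, i_ca) == \
            pytest.approx(0.0, abs=1e-15)
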