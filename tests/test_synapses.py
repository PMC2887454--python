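"""Synaptic mechanisms: waveforms, Mg block, STP, STDP, gap junctions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nml1 import synapses as syn


class TestConductanceWaveform:
    def test_zero_at_event_time_when_rise_is_finite(self):
        s = syn.DoubleExpSynapse("s", 1.0, 0.0, rise_time=0.5,
                                 decay_times=(3.0,))
        assert s.conductance_at(0.0) == 0.0

    def test_instantaneous_rise_starts_at_peak(self):
        s = syn.DoubleExpSynapse("s", 2.0, 0.0, rise_time=0.0,
                                 decay_times=(3.0,))
        assert s.conductance_at(0.0) == pytest.approx(2.0)

    def test_peak_time_and_amplitude_closed_form(self):
        """t* = (tau_r tau_d / (tau_d - tau_r)) ln(tau_d/tau_r) and
        g(t*) = g_max; cross-checked against a dense grid search."""
        tau_r, tau_d, gmax = 0.5, 4.0, 1.7
        s = syn.DoubleExpSynapse("s", gmax, 0.0, rise_time=tau_r,
                                 decay_times=(tau_d,))
        t_star = tau_r * tau_d / (tau_d - tau_r) * math.log(tau_d / tau_r)
        assert s.conductance_at(t_star) == pytest.approx(gmax, rel=1e-12)
        grid = np.linspace(0, 30, 300001)
        g = s.conductance_at(grid)
        assert g.max() == pytest.approx(gmax, rel=1e-8)
        assert grid[np.argmax(g)] == pytest.approx(t_star, abs=1e-3)

    def test_alpha_function_degenerate_limit(self):
        s = syn.DoubleExpSynapse("s", 1.0, 0.0, rise_time=2.0,
                                 decay_times=(2.0,))
        assert s.conductance_at(2.0) == pytest.approx(1.0)   # peak at tau
        assert s.conductance_at(0.0) == 0.0

    def test_triple_decay_peaks_at_max_conductance(self):
        s = syn.DoubleExpSynapse("s", 1.0, 0.0, rise_time=0.3,
                                 decay_times=(2.0, 10.0, 50.0),
                                 decay_fractions=(0.5, 0.3, 0.2))
        grid = np.linspace(0, 200, 400001)
        g = s.conductance_at(grid)
        assert g.max() == pytest.approx(1.0, rel=1e-6)
        assert np.all(g >= 0.0)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(syn.SynapseError):
            syn.DoubleExpSynapse("s", 1.0, 0.0, 0.1, (2.0, 5.0),
                                 (0.5, 0.4))


class TestMgBlock:
    def block(self):
        return syn.MgBlock(mg_concentration=1.0, eta=0.28, gamma=0.062)

    def test_no_magnesium_means_no_block(self):
        b = syn.MgBlock(0.0, 0.28, 0.062)
        for v in (-100.0, 0.0, 60.0):
            assert b.factor(v) == 1.0

    def test_monotone_increasing_with_saturating_limits(self):
        grid = np.linspace(-150, 150, 301)
        f = self.block().factor(grid)
        assert np.all(np.diff(f) > 0)
        assert f[0] < 0.01 and f[-1] > 0.99
        assert np.all((f > 0) & (f <= 1))

    def test_value_at_zero_millivolts(self):
        # direct substitution: 1 / (1 + eta [Mg])
        assert self.block().factor(0.0) == pytest.approx(1 / 1.28)


class TestSTP:
    def synapse(self, tau_rec, tau_fac, U=0.5):
        base = syn.DoubleExpSynapse("s", 1.0, 0.0, 0.0, (3.0,))
        return syn.STPSynapse(base=base, utilisation=U, tau_rec=tau_rec,
                              tau_fac=tau_fac)

    def releases(self, s, isi=20.0, n=12):
        state = s.initial_state()
        out = []
        for k in range(n):
            r, state = s.on_spike(state, isi * (k + 1))
            out.append(r)
        return out

    def test_both_time_constants_zero_disables_plasticity(self):
        rels = self.releases(self.synapse(0.0, 0.0))
        assert all(r == pytest.approx(rels[0]) for r in rels)
        s = self.synapse(0.0, 0.0)
        assert s.event_scale(rels[0]) == pytest.approx(1.0)

    def test_recovery_120ms_depresses_monotonically(self):
        rels = self.releases(self.synapse(120.0, 0.0))
        assert all(b < a for a, b in zip(rels, rels[1:]))

    def test_facilitation_300ms_facilitates_monotonically(self):
        rels = self.releases(self.synapse(0.0, 300.0, U=0.1))
        assert all(b > a for a, b in zip(rels, rels[1:]))

    def test_depression_fixed_point_matches_long_run(self):
        """Periodic train, tau_fac = 0: the x-map has the closed-form
        fixed point x* = (1 - e)/(1 - (1-U) e), e = exp(-T/tau_rec)."""
        U, tau_rec, T = 0.5, 120.0, 20.0
        s = self.synapse(tau_rec, 0.0, U=U)
        rels = self.releases(s, isi=T, n=400)
        e = math.exp(-T / tau_rec)
        x_star = (1 - e) / (1 - (1 - U) * e)
        assert rels[-1] == pytest.approx(U * x_star, rel=1e-9)

    def test_release_fraction_stays_in_unit_interval(self):
        for s in (self.synapse(120.0, 0.0), self.synapse(0.0, 300.0, 0.1),
                  self.synapse(80.0, 200.0, 0.3)):
            state = s.initial_state()
            t = 0.0
            rng = np.random.default_rng(7)
            for _ in range(200):
                t += rng.exponential(15.0) + 1e-3
                r, state = s.on_spike(state, t)
                assert 0.0 <= r <= 1.0
                assert 0.0 <= state.x <= 1.0 and 0.0 <= state.u <= 1.0

    def test_non_increasing_spike_times_rejected(self):
        s = self.synapse(120.0, 0.0)
        _, state = s.on_spike(s.initial_state(), 10.0)
        with pytest.raises(syn.SynapseError):
            s.on_spike(state, 10.0)


def naive_stdp_replay(s: syn.STDPSynapse, pres, posts):
    """O(n^2) all-to-all pairwise oracle processing events in time order
    with hard clipping after every update."""
    events = sorted([(t, "pre") for t in pres]
                    + [(t, "post") for t in posts])
    w = s.initial_weight
    for t, kind in events:
        if kind == "pre":
            depress = sum(math.exp(-(t - tp) / s.tau_minus)
                          for tp in posts if tp <= t)
            w = min(max(w - s.a_minus * s.w_max * depress, 0.0), s.w_max)
        else:
            potentiate = sum(math.exp(-(t - tp) / s.tau_plus)
                             for tp in pres if tp <= t)
            w = min(max(w + s.a_plus * s.w_max * potentiate, 0.0), s.w_max)
    return w


class TestSTDP:
    def synapse(self):
        return syn.STDPSynapse(id="stdp", w_max=1.0, a_plus=0.05,
                               a_minus=0.055, tau_plus=20.0,
                               tau_minus=20.0, initial_weight=0.5)

    def test_pre_alone_leaves_weight_unchanged(self):
        s = self.synapse()
        state = s.on_pre(s.initial_state(), 10.0)
        assert state.weight == 0.5

    def test_coincident_pair_gives_maximal_potentiation(self):
        s = self.synapse()
        state = s.on_pre(s.initial_state(), 10.0)
        state = s.on_post(state, 10.0 + 1e-12)
        assert state.weight == pytest.approx(0.5 + 0.05 * 1.0)

    def test_post_before_pre_depresses(self):
        s = self.synapse()
        state = s.on_post(s.initial_state(), 10.0)
        state = s.on_pre(state, 15.0)
        expected = 0.5 - 0.055 * math.exp(-5.0 / 20.0)
        assert state.weight == pytest.approx(expected)

    def test_random_trains_match_pairwise_replay(self):
        rng = np.random.default_rng(11)
        s = self.synapse()
        pres = np.sort(rng.uniform(0, 500, 40))
        posts = np.sort(rng.uniform(0, 500, 40))
        events = sorted([(t, "pre") for t in pres]
                        + [(t, "post") for t in posts])
        state = s.initial_state()
        for t, kind in events:
            state = (s.on_pre if kind == "pre" else s.on_post)(state, t)
        assert state.weight == pytest.approx(
            naive_stdp_replay(s, list(pres), list(posts)), abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10_000),
           a_plus=st.floats(min_value=0.0, max_value=0.5),
           a_minus=st.floats(min_value=0.0, max_value=0.5))
    def test_weight_confined_to_bounds_on_random_trains(self, seed, a_plus,
                                                        a_minus):
        s = syn.STDPSynapse(id="s", w_max=1.0, a_plus=a_plus,
                            a_minus=a_minus, tau_plus=15.0, tau_minus=30.0,
                            initial_weight=0.5)
        rng = np.random.default_rng(seed)
        state = s.initial_state()
        t_pre = t_post = 0.0
        for _ in range(100):
            if rng.random() < 0.5:
                t_pre += rng.exponential(10.0)
                state = s.on_pre(state, max(t_pre, state.t_pre))
            else:
                t_post += rng.exponential(10.0)
                state = s.on_post(state, max(t_post, state.t_post))
            assert 0.0 <= state.weight <= 1.0


class TestGapJunction:
    def test_no_current_without_voltage_difference(self):
        gj = syn.GapJunction("g", 3e-4)
        assert gj.current_into_a(-65.0, -65.0) == 0.0

    def test_300_pS_at_10_mV_gives_3_pA(self):
        # unit arithmetic: 300 pS * 10 mV = 3 pA = 0.003 nA
        gj = syn.GapJunction("g", 300e-6)   # uS
        assert gj.current_into_a(-70.0, -60.0) == pytest.approx(3e-3)

    def test_currents_are_exactly_antisymmetric(self):
        gj = syn.GapJunction("g", 3e-4)
        for va, vb in [(-70.0, -60.0), (-65.0, -65.0), (30.0, -80.0)]:
            assert gj.current_into_a(va, vb) + gj.current_into_a(vb, va) \
                == 0.0

    def test_two_passive_cells_steady_state_solves_balance(self):
        """0.19 nA step into cell 1 of a coupled passive pair: the steady
        voltages satisfy the 2x2 conductance balance (linear-system
        oracle)."""
        g_l, g_j, e_l, i = 0.02356194490192345, 300e-6, -65.0, 0.19
        a = np.array([[g_l + g_j, -g_j], [-g_j, g_l + g_j]])
        rhs = np.array([g_l * e_l + i, g_l * e_l])
        v1, v2 = np.linalg.solve(a, rhs)
        # balance residuals vanish
        assert g_l * (v1 - e_l) == pytest.approx(
            i + g_j * (v2 - v1), rel=1e-12)
        assert g_l * (v2 - e_l) == pytest.approx(g_j * (v1 - v2), rel=1e-9)
        assert v1 > v2 > e_l
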