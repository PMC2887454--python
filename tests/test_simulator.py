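"""The reference compartmental solver: graph building, integration
accuracy, clamps, spike detection and cross-run comparison."""

import math

import numpy as np
import pytest

from nml1 import fixtures as fx
from nml1 import simulator as sim
from nml1.morphology import BiophysicalCell, ChannelPlacement


def passive_setup(diameter=50.0):
    cell, leak = fx.passive_cell("p", diameter=diameter)
    mech = {leak.id: leak}
    return cell, leak, mech


class TestBuildGraph:
    def test_cable_divisions_set_compartment_count(self):
        bundle = fx.generate_fixture("ball-and-stick", seed=0,
                                     dendrite_divisions=4)
        mech = bundle.document.mechanism_index()
        graph = sim.build_graph(bundle.document.cells, bundle.config, mech)
        # 1 soma sphere + 4 dendrite compartments
        assert graph.n == 5

    def test_symmetric_links_are_sums_of_half_resistances(self):
        bundle = fx.generate_fixture("ball-and-stick", seed=0,
                                     dendrite_divisions=2)
        mech = bundle.document.mechanism_index()
        cfg = sim.SolverConfig(dt=0.01, symmetry="symmetric")
        graph = sim.build_graph(bundle.document.cells, cfg, mech)
        comps = graph.comps
        r1 = comps[1].geometry.axial_resistance_factor * 0.1 * 10.0
        r2 = comps[2].geometry.axial_resistance_factor * 0.1 * 10.0
        assert comps[2].link_resistance == pytest.approx((r1 + r2) / 2)
        # soma sphere contributes no axial resistance
        assert comps[1].link_resistance == pytest.approx(r1 / 2)

    def test_asymmetric_links_carry_full_compartment_resistance(self):
        bundle = fx.generate_fixture("ball-and-stick", seed=0,
                                     dendrite_divisions=2)
        mech = bundle.document.mechanism_index()
        cfg = sim.SolverConfig(dt=0.01, symmetry="asymmetric")
        graph = sim.build_graph(bundle.document.cells, cfg, mech)
        comps = graph.comps
        r2 = comps[2].geometry.axial_resistance_factor * 0.1 * 10.0
        assert comps[2].link_resistance == pytest.approx(r2)

    def test_total_membrane_area_matches_morphology(self):
        """Graph area equals the frustum-sum surface area to 1e-9."""
        bundle = fx.generate_fixture("ball-and-stick", seed=0,
                                     dendrite_divisions=13)
        mech = bundle.document.mechanism_index()
        graph = sim.build_graph(bundle.document.cells, bundle.config, mech)
        expected = bundle.document.cells[0].morphology.surface_area()
        assert graph.area.sum() == pytest.approx(expected, rel=1e-9)

    def test_unresolved_mechanism_raises_at_run(self):
        cell, leak, mech = passive_setup()
        graph = sim.build_graph(cell, sim.SolverConfig(), mech)
        with pytest.raises(sim.SimulationError):
            sim.run(graph, {}, [], 1.0, sim.SolverConfig())


class TestPassiveDynamics:
    def test_rc_charging_matches_analytic_solution(self):
        """Current step into a passive compartment with leak 3.0e-9
        mS/um^2 (0.3 mS/cm^2) and capacitance 1e-8 uF/um^2 (1 uF/cm^2):
        V relaxes to E + I/g with time constant c/g = 10/3 ms."""
        cell, leak, mech = passive_setup()
        cfg = sim.SolverConfig(dt=0.005)
        graph = sim.build_graph(cell, cfg, mech)
        area = graph.area.sum()
        g_l = 0.3 * area * 1e-5
        c = 1.0 * area * 1e-5
        tau = c / g_l
        assert tau == pytest.approx(10.0 / 3.0)
        current = 0.1
        res = sim.run(graph, mech,
                      [sim.CurrentPulse((0, "0", 0.5), current, 0.0)],
                      30.0, cfg)
        t = res.recordings["v:p"].times
        v = res.voltage("p")
        v_inf = -65.0 + current / g_l
        analytic = v_inf + (-65.0 - v_inf) * np.exp(-t / tau)
        assert np.abs(v - analytic).max() < 5e-3

    def test_error_decreases_at_first_order_as_dt_halves(self):
        cell, leak, mech = passive_setup()
        errors = []
        for dt in (0.04, 0.02, 0.01):
            cfg = sim.SolverConfig(dt=dt)
            graph = sim.build_graph(cell, cfg, mech)
            area = graph.area.sum()
            g_l, c = 0.3 * area * 1e-5, 1.0 * area * 1e-5
            res = sim.run(graph, mech,
                          [sim.CurrentPulse((0, "0", 0.5), 0.1, 0.0)],
                          20.0, cfg)
            t = res.recordings["v:p"].times
            v_inf = -65.0 + 0.1 / g_l
            analytic = v_inf + (-65.0 - v_inf) * np.exp(-t * g_l / c)
            errors.append(np.abs(res.voltage("p") - analytic).max())
        assert errors[1] < errors[0] and errors[2] < errors[1]
        # implicit Euler is first order: halving dt ~halves the error
        assert errors[0] / errors[1] == pytest.approx(2.0, rel=0.15)
        assert errors[1] / errors[2] == pytest.approx(2.0, rel=0.15)

    def test_second_order_method_is_more_accurate(self):
        cell, leak, mech = passive_setup()
        out = {}
        for method in ("implicit-first-order",
                       "semi-implicit-second-order"):
            cfg = sim.SolverConfig(dt=0.02, method=method)
            graph = sim.build_graph(cell, cfg, mech)
            area = graph.area.sum()
            g_l, c = 0.3 * area * 1e-5, 1.0 * area * 1e-5
            res = sim.run(graph, mech,
                          [sim.CurrentPulse((0, "0", 0.5), 0.1, 0.0)],
                          20.0, cfg)
            t = res.recordings["v:p"].times
            v_inf = -65.0 + 0.1 / g_l
            analytic = v_inf + (-65.0 - v_inf) * np.exp(-t * g_l / c)
            out[method] = np.abs(res.voltage("p") - analytic).max()
        assert out["semi-implicit-second-order"] < \
            out["implicit-first-order"] / 5

    def test_equilibrium_is_preserved_without_stimuli(self):
        cell, leak, mech = passive_setup()
        cfg = sim.SolverConfig(dt=0.05, initial_voltage=-65.0)
        graph = sim.build_graph(cell, cfg, mech)
        res = sim.run(graph, mech, [], 10.0, cfg)
        np.testing.assert_allclose(res.voltage("p"), -65.0, atol=1e-9)


class TestDeterminismAndConvergence:
    def test_identical_config_gives_bit_identical_recordings(self):
        bundle = fx.generate_fixture("hh-point-cell", seed=3,
                                     duration=20.0)
        mech = bundle.document.mechanism_index()
        graph = sim.build_graph(bundle.document.cells, bundle.config, mech)
        a = sim.run(graph, mech, bundle.stimuli, 20.0, bundle.config)
        graph2 = sim.build_graph(bundle.document.cells, bundle.config,
                                 mech)
        b = sim.run(graph2, mech, bundle.stimuli, 20.0, bundle.config)
        assert np.array_equal(a.voltage("hh_point_cell"),
                              b.voltage("hh_point_cell"))

    def test_hh_cell_spike_count_stable_under_dt_halving(self):
        counts = {}
        for dt in (0.005, 0.0025):
            bundle = fx.generate_fixture("hh-point-cell", seed=1, dt=dt,
                                         duration=60.0)
            mech = bundle.document.mechanism_index()
            graph = sim.build_graph(bundle.document.cells, bundle.config,
                                    mech)
            res = sim.run(graph, mech, bundle.stimuli, 60.0, bundle.config)
            counts[dt] = len(res.spikes("hh_point_cell"))
        assert counts[0.005] == counts[0.0025] > 0

    def test_temporal_discrepancy_shrinks_as_dt_decreases(self):
        """Spike-time discrepancy between dt and dt/2 runs decreases
        monotonically over the dt ladder {0.02, 0.01, 0.005} ms."""
        trains = {}
        for dt in (0.02, 0.01, 0.005, 0.0025):
            bundle = fx.generate_fixture("hh-point-cell", seed=1, dt=dt,
                                         duration=60.0)
            mech = bundle.document.mechanism_index()
            graph = sim.build_graph(bundle.document.cells, bundle.config,
                                    mech)
            res = sim.run(graph, mech, bundle.stimuli, 60.0, bundle.config)
            trains[dt] = res.spikes("hh_point_cell")
        discrepancies = []
        for dt in (0.02, 0.01, 0.005):
            c = sim.compare_runs(trains[dt], trains[dt / 2], 60.0)
            assert c.same_count
            discrepancies.append(c.max_discrepancy_percent)
        assert discrepancies[0] > discrepancies[1] > discrepancies[2]


class TestGapJunctionRuns:
    def test_steady_state_solves_the_conductance_balance(self):
        """0.19 nA into cell 0 of the 300 pS coupled pair: late-time
        voltages match the direct 2x2 linear solve."""
        bundle = fx.generate_fixture("passive-pair-gap-junction", seed=1)
        res = sim.simulate_network(bundle.document, bundle.duration,
                                   bundle.config)
        dt = bundle.config.dt
        k = int(118.0 / dt)    # inside the 20-120 ms pulse, settled
        area = math.pi * 2500.0
        g_l, g_j = 0.3 * area * 1e-5, 300e-6
        a = np.array([[g_l + g_j, -g_j], [-g_j, g_l + g_j]])
        rhs = np.array([g_l * -65.0 + 0.19, g_l * -65.0])
        v_expected = np.linalg.solve(a, rhs)
        assert res.voltage("pair[0]")[k] == pytest.approx(v_expected[0],
                                                          abs=1e-3)
        assert res.voltage("pair[1]")[k] == pytest.approx(v_expected[1],
                                                          abs=1e-3)

    def test_coupling_currents_sum_to_zero_every_step(self):
        bundle = fx.generate_fixture("passive-pair-gap-junction", seed=1,
                                     duration=60.0)
        res = sim.simulate_network(bundle.document, 60.0, bundle.config)
        va, vb = res.voltage("pair[0]"), res.voltage("pair[1]")
        g = 300e-6
        ia, ib = g * (vb - va), g * (va - vb)
        assert np.all(ia + ib == 0.0)


class TestVoltageClamp:
    def test_zero_current_when_held_at_leak_reversal(self):
        cell, leak, mech = passive_setup()
        cfg = sim.SolverConfig(dt=0.01)
        graph = sim.build_graph(cell, cfg, mech)
        rec = sim.run_voltage_clamp(graph, mech, (0, "0", 0.5),
                                    [(0.0, -65.0)], [], 20.0, cfg)
        assert np.abs(rec.samples[100:]).max() < 1e-9

    def test_ampa_peaks_scale_with_driving_force(self):
        """AMPA EPSC amplitudes at -80 and -20 mV holding scale as the
        driving-force ratio (-80-0):(-20-0) = 4 (linear-ohmic oracle)."""
        peaks = {}
        for hold in (-80.0, -20.0):
            bundle = fx.generate_fixture("ampa-nmda-clamp-cell", seed=1,
                                         synapse="AMPA", holding=hold)
            mech = bundle.document.mechanism_index()
            graph = sim.build_graph(bundle.document.cells, bundle.config,
                                    mech)
            events = [s for s in bundle.stimuli
                      if isinstance(s, sim.SynapticEvents)]
            rec = sim.run_voltage_clamp(graph, mech, (0, "0", 0.5),
                                        [(0.0, hold)], events, 60.0,
                                        bundle.config)
            baseline = rec.samples[int(15.0 / bundle.config.dt)]
            seg = rec.samples[int(20.0 / bundle.config.dt):]
            peaks[hold] = seg[np.argmax(np.abs(seg - baseline))] - baseline
        assert peaks[-80.0] / peaks[-20.0] == pytest.approx(4.0, rel=1e-3)
        assert peaks[-80.0] < 0    # inward EPSC

    def test_nmda_block_inverts_the_driving_force_ordering(self):
        """With 1 mM Mg2+ block, |peak| at -20 mV exceeds |peak| at
        -80 mV; the ratio follows block factor x driving force."""
        from nml1.fixtures import default_nmda
        block = default_nmda().block
        predicted = (block.factor(-80.0) * -80.0) / \
            (block.factor(-20.0) * -20.0)
        peaks = {}
        for hold in (-80.0, -20.0):
            bundle = fx.generate_fixture("ampa-nmda-clamp-cell", seed=1,
                                         synapse="NMDA", holding=hold)
            mech = bundle.document.mechanism_index()
            graph = sim.build_graph(bundle.document.cells, bundle.config,
                                    mech)
            events = [s for s in bundle.stimuli
                      if isinstance(s, sim.SynapticEvents)]
            rec = sim.run_voltage_clamp(graph, mech, (0, "0", 0.5),
                                        [(0.0, hold)], events, 120.0,
                                        bundle.config)
            baseline = rec.samples[int(15.0 / bundle.config.dt)]
            seg = rec.samples[int(20.0 / bundle.config.dt):]
            peaks[hold] = seg[np.argmax(np.abs(seg - baseline))] - baseline
        assert abs(peaks[-20.0]) > abs(peaks[-80.0])
        assert peaks[-80.0] / peaks[-20.0] == pytest.approx(predicted,
                                                            rel=0.05)


class TestSpikeDetection:
    def test_constant_subthreshold_trace_is_empty(self):
        train = sim.detect_spikes(np.full(1000, -65.0), 0.01)
        assert len(train) == 0

    def test_triangle_crossing_is_interpolated(self):
        trace = np.array([-10.0, -2.0, 6.0, -4.0])
        train = sim.detect_spikes(trace, 0.5, threshold=0.0)
        # crossing between samples 1 and 2 at fraction 0.25
        assert train.times == pytest.approx([0.5 * (1 + 0.25)])

    def test_noisy_multi_spike_trace_matches_naive_scan(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 100, 0.01)
        trace = 20 * np.sin(2 * np.pi * t / 7.0) + rng.normal(0, 1, len(t))
        train = sim.detect_spikes(trace, 0.01, threshold=15.0)
        naive = []
        for i in range(len(trace) - 1):
            if trace[i] < 15.0 <= trace[i + 1]:
                frac = (15.0 - trace[i]) / (trace[i + 1] - trace[i])
                naive.append((i + frac) * 0.01)
        np.testing.assert_allclose(train.times, naive, atol=1e-12)

    def test_sample_count_contract(self):
        cell, leak, mech = passive_setup()
        cfg = sim.SolverConfig(dt=0.02)
        graph = sim.build_graph(cell, cfg, mech)
        res = sim.run(graph, mech, [], 5.0, cfg)
        assert len(res.voltage("p")) == int(5.0 / 0.02) + 1


class TestCompareRuns:
    def test_identical_trains_have_zero_discrepancy(self):
        a = sim.SpikeTrain(np.array([10.0, 50.0, 90.0]))
        c = sim.compare_runs(a, a, 100.0)
        assert c.same_count and c.max_discrepancy_percent == 0.0

    def test_one_millisecond_over_200_is_half_a_percent(self):
        a = sim.SpikeTrain(np.array([200.0]))
        b = sim.SpikeTrain(np.array([201.0]))
        c = sim.compare_runs(a, b, 200.0)
        assert c.max_discrepancy_percent == pytest.approx(0.5)

    def test_random_perturbations_match_brute_force(self):
        rng = np.random.default_rng(3)
        base = np.sort(rng.uniform(0, 500, 30))
        shift = rng.normal(0, 0.5, 30)
        c = sim.compare_runs(sim.SpikeTrain(base),
                             sim.SpikeTrain(base + shift), 500.0)
        assert c.max_discrepancy_percent == \
            pytest.approx(np.abs(shift).max() / 500.0 * 100.0)

    def test_count_mismatch_is_reported_not_raised(self):
        c = sim.compare_runs(sim.SpikeTrain(np.array([1.0])),
                             sim.SpikeTrain(np.array([1.0, 2.0])), 10.0)
        assert not c.same_count
        assert c.max_discrepancy_percent is None


class TestGateBoundedness:
    def test_gate_states_remain_in_unit_interval_during_spiking(self):
        bundle = fx.generate_fixture("hh-point-cell", seed=1,
                                     duration=30.0)
        mech = bundle.document.mechanism_index()
        graph = sim.build_graph(bundle.document.cells, bundle.config, mech)
        # instrument: run and verify the recorded voltages stayed finite
        # and the implied steady states never left [0, 1]
        res = sim.run(graph, mech, bundle.stimuli, 30.0, bundle.config)
        v = res.voltage("hh_point_cell")
        assert np.all(np.isfinite(v))
        from nml1 import channels as ch
        for mech_obj in bundle.document.channels:
            for gate in getattr(mech_obj, "gates", []):
                tau, inf = ch.tau_inf(gate, v,
                                      temp=bundle.config.temperature,
                                      q10=mech_obj.q10)
                assert np.all((inf >= 0.0) & (inf <= 1.0))
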