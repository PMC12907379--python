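"""Tests of the spiking network layer: wiring, synapses, event delivery."""

import numpy as np
import pytest

from neurocosim.ion_neuron import IonNeuronParams, detect_spikes, integrate
from neurocosim.micro_net import (MicroNetwork, NetworkSpec, SpikeEvent,
                                  SynapseParams, build_weight_matrix,
                                  synaptic_current)


class TestBuild:
    def test_mixture_counts_and_connections(self):
        spec = NetworkSpec(N=100, f=0.2, seed=0)
        net = MicroNetwork(spec)
        assert (net.kbath == spec.kbath_sle).sum() == 20
        assert (net.kbath == spec.kbath_tonic).sum() == 80
        assert (net.W > 0).sum() == 100 * 99
        assert np.all(np.diag(net.W) == 0)

    def test_unconnected_topology(self):
        net = MicroNetwork(NetworkSpec(N=10, topology="none"))
        assert not np.any(net.W)

    @pytest.mark.parametrize("seed", [0, 1, 7])
    def test_truncated_normal_weights_positive(self, seed):
        spec = NetworkSpec(N=30, weight_mode="truncated_normal", seed=seed)
        w = build_weight_matrix(spec)
        off = w[~np.eye(30, dtype=bool)]
        assert np.all(off > 0)

    def test_weight_matrix_deterministic_in_seed(self):
        spec = NetworkSpec(N=20, weight_mode="truncated_normal", seed=3)
        assert np.array_equal(build_weight_matrix(spec),
                              build_weight_matrix(spec))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(N=0)
        with pytest.raises(ValueError):
            NetworkSpec(f=1.5)
        with pytest.raises(ValueError):
            NetworkSpec(topology="ring")


class TestSynapse:
    def test_zero_conductance_zero_current(self):
        assert synaptic_current(0.0, -70.0, 0.0) == 0.0

    def test_depolarizing_below_reversal(self):
        assert synaptic_current(1.0, -70.0, 0.0) > 0

    def test_single_delivery_exponential_decay(self):
        """g_syn after one delivery follows w*exp(-(t-t_d)/tau)."""
        spec = NetworkSpec(N=2, f=0.0, topology="none")
        syn = SynapseParams(tau_syn=2.0, delay=1.0)
        net = MicroNetwork(spec, synapse=syn, dt=0.05)
        ev = SpikeEvent(source=-1, time=5.0, weight=0.5, delay=0.0)
        net.advance(5.0)
        g_before = net.gsyn.copy()
        net.advance(25.0, external_events=[ev])
        # analytic value at t=25: jump of 0.5 at t=5, decayed 20 ms
        expected = (g_before[0] + 0.5) * np.exp(-20.0 / 2.0)
        assert net.gsyn[0] == pytest.approx(expected, rel=1e-9)

    def test_two_deliveries_superpose(self):
        spec = NetworkSpec(N=1, f=0.0, topology="none")
        syn = SynapseParams(tau_syn=3.0)
        net = MicroNetwork(spec, synapse=syn, dt=0.05)
        evs = [SpikeEvent(-1, 2.0, 0.4, 0.0), SpikeEvent(-1, 6.0, 0.3, 0.0)]
        net.advance(10.0, external_events=evs)
        expected = 0.4 * np.exp(-8.0 / 3.0) + 0.3 * np.exp(-4.0 / 3.0)
        assert net.gsyn[0] == pytest.approx(expected, rel=1e-9)


class TestAdvance:
    def test_decoupled_equals_isolated(self, default_params, rest):
        """Unconnected cells reproduce single-cell integration exactly."""
        spec = NetworkSpec(N=3, f=1.0, kbath_sle=17.0, topology="none")
        net = MicroNetwork(spec, neuron=default_params, dt=0.05,
                           initial_state=rest)
        (t_net, c_net), _ = net.advance(3000.0)
        single = integrate(default_params.with_kbath(17.0), rest, 3000.0,
                           dt=0.05)
        for j in range(3):
            cell_spikes = t_net[c_net == j]
            assert np.allclose(cell_spikes, single.spikes[0], atol=1e-9)

    def test_zero_weights_equal_no_topology(self, rest):
        spec_a = NetworkSpec(N=4, f=0.5, topology="none")
        spec_b = NetworkSpec(N=4, f=0.5, topology="all_to_all", w=0.0)
        na = MicroNetwork(spec_a, dt=0.05, initial_state=rest)
        nb = MicroNetwork(spec_b, dt=0.05, initial_state=rest)
        na.advance(2000.0)
        nb.advance(2000.0)
        assert np.array_equal(na.V, nb.V)

    def test_pause_resume_equivalence(self, rest):
        spec = NetworkSpec(N=5, f=0.4, seed=2)
        one = MicroNetwork(spec, dt=0.05, initial_state=rest)
        two = MicroNetwork(spec, dt=0.05, initial_state=rest)
        one.advance(2000.0)
        two.advance(700.0)
        two.advance(1200.0)
        two.advance(2000.0)
        assert np.array_equal(one.V, two.V)
        assert np.array_equal(one.gsyn, two.gsyn)
        ta, _ = one.population_spikes()
        tb, _ = two.population_spikes()
        assert np.array_equal(ta, tb)

    def test_determinism_bit_identical(self, rest):
        spec = NetworkSpec(N=8, f=0.25, weight_mode="truncated_normal",
                           seed=11)
        runs = []
        for _ in range(2):
            net = MicroNetwork(spec, dt=0.05, initial_state=rest)
            net.advance(1500.0)
            runs.append(net.population_spikes())
        assert np.array_equal(runs[0][0], runs[1][0])
        assert np.array_equal(runs[0][1], runs[1][1])

    def test_event_in_past_rejected(self, rest):
        net = MicroNetwork(NetworkSpec(N=2, topology="none"), dt=0.05,
                           initial_state=rest)
        net.advance(100.0)
        with pytest.raises(ValueError, match="before current time"):
            net.advance(200.0,
                        external_events=[SpikeEvent(0, 10.0, 0.5, 0.0)])

    def test_identical_sle_cells_stay_identical(self, default_params,
                                                rest):
        """All-SLE all-to-all cells from one state receive identical input
        and remain synchronised."""
        spec = NetworkSpec(N=6, f=1.0, kbath_sle=17.0)
        net = MicroNetwork(spec, neuron=default_params, dt=0.05,
                           initial_state=rest)
        net.advance(4000.0)
        assert np.ptp(net.V) < 1e-9
        assert np.ptp(net.dki) < 1e-12


class TestReconfigure:
    def test_identity_reconfigure_is_noop(self, rest):
        spec = NetworkSpec(N=5, f=0.4, seed=8)
        a = MicroNetwork(spec, dt=0.05, initial_state=rest)
        b = MicroNetwork(spec, dt=0.05, initial_state=rest)
        a.advance(1000.0)
        b.advance(1000.0)
        b.reconfigure(new_adjacency=b.W.copy())
        a.advance(2000.0)
        b.advance(2000.0)
        assert np.array_equal(a.V, b.V)

    def test_disconnect_decouples(self, rest):
        spec = NetworkSpec(N=4, f=0.5, seed=3)
        net = MicroNetwork(spec, dt=0.05, initial_state=rest)
        net.advance(500.0)
        net.reconfigure(topology="none")
        assert not np.any(net.W)

    def test_shape_mismatch_rejected(self, rest):
        net = MicroNetwork(NetworkSpec(N=4), dt=0.05, initial_state=rest)
        with pytest.raises(ValueError):
            net.reconfigure(new_adjacency=np.ones((3, 3)))


class TestPopulationSpikes:
    def test_silent_network_empty(self, quiescent):
        p, asleep = quiescent
        net = MicroNetwork(NetworkSpec(N=3, f=0.0, kbath_tonic=2.5,
                                       topology="none"),
                           neuron=p, dt=0.05, initial_state=asleep)
        net.advance(1000.0)
        t, c = net.population_spikes()
        assert t.size == 0

    def test_single_cell_count_matches_detector(self, default_params,
                                                rest):
        spec = NetworkSpec(N=1, f=1.0, kbath_sle=9.5, topology="none")
        net = MicroNetwork(spec, neuron=default_params, dt=0.05,
                           initial_state=rest)
        (t, c), V = net.advance(8000.0, sample_every=1)
        from_trace = detect_spikes(V[:, 0], threshold=0.0, dt=0.05)
        assert abs(t.size - from_trace.size) <= 1

    def test_ordering_stable(self, rest):
        net = MicroNetwork(NetworkSpec(N=10, f=0.5, seed=5), dt=0.05,
                           initial_state=rest)
        net.advance(2000.0)
        t, c = net.population_spikes()
        order = np.lexsort((c, t))
        assert np.array_equal(order, np.arange(t.size))
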