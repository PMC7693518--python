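import dataclasses
import itertools

import numpy as np
import pytest

from spikecube import classifier, encoding, io, reservoir, synthetic
from spikecube.encoding import SpikeTrainSet
from spikecube.reservoir import (
    ReservoirGeometry,
    ReservoirNet,
    build_geometry,
    init_connections,
    run_sample,
    train_stdp,
)

from _reference import random_spike_train_set, reference_simulate


def spike_train(channel, times, pols, T):
    return SpikeTrainSet(
        channel_names=(channel,),
        times=(np.array(times, dtype=np.int64),),
        polarities=(np.array(pols, dtype=np.int8),),
        n_timepoints=T,
    )


class TestGeometry:
    def test_full_grid(self):
        geom = build_geometry(1000, (10, 10, 10))
        assert geom.coords.shape == (1000, 3)
        assert len({tuple(c) for c in geom.coords}) == 1000

    def test_input_map_injective_and_anatomical(self):
        geom = build_geometry(1000, (10, 10, 10), ("FP1", "F3", "C4", "C3"))
        sites = list(geom.input_map.values())
        assert len(set(sites)) == 4
        fp1 = geom.coords[geom.input_map["FP1"]]
        c3 = geom.coords[geom.input_map["C3"]]
        c4 = geom.coords[geom.input_map["C4"]]
        # FP1 is frontal relative to the central electrodes; C3/C4 straddle the midline
        assert fp1[1] > c3[1]
        assert c3[0] < c4[0]

    def test_222_pairwise_distances(self):
        geom = build_geometry(8, (2, 2, 2), channels=("FP1",))
        dists = {
            round(float(np.linalg.norm(a - b)), 6)
            for a, b in itertools.combinations(geom.coords, 2)
        }
        assert dists == {1.0, round(np.sqrt(2), 6), round(np.sqrt(3), 6)}

    def test_shape_mismatch_and_unknown_channel(self):
        with pytest.raises(ValueError, match="grid_shape"):
            build_geometry(999, (10, 10, 10))
        with pytest.raises(ValueError, match="XX9"):
            build_geometry(27, (3, 3, 3), channels=("XX9",))


class TestWiring:
    def test_distance_constraint(self, small_net):
        pre, post = np.nonzero(small_net.signs)
        d = np.linalg.norm(
            small_net.geometry.coords[pre] - small_net.geometry.coords[post], axis=1
        )
        assert np.all(d <= small_net.radius + 1e-12)
        assert np.all(np.diag(small_net.signs) == 0)

    def test_corner_neuron_outdegree_on_unit_radius(self):
        geom = build_geometry(27, (3, 3, 3), channels=("FP1",))
        net = init_connections(geom, radius=1.01, conn_prob=1.0, seed=0)
        corner = int(np.argmin(np.linalg.norm(geom.coords, axis=1)))  # (0,0,0)
        assert np.count_nonzero(net.signs[corner]) == 3

    def test_magnitude_range_and_inhibitory_mix(self, small_geometry):
        net = init_connections(small_geometry, radius=2.5, conn_prob=1.0,
                               inhibitory_fraction=0.25, seed=3, w0=0.2)
        mags = net.magnitudes[net.signs != 0]
        pre, post = np.nonzero(net.signs)
        d = np.linalg.norm(
            net.geometry.coords[pre] - net.geometry.coords[post], axis=1
        )
        assert np.all(mags > 0)
        assert np.all(mags <= np.minimum(0.2 / d, net.w_cap) + 1e-12)
        frac_neg = np.mean(net.signs[net.signs != 0] < 0)
        assert 0.1 < frac_neg < 0.4

    def test_seeded_determinism(self, small_geometry):
        a = init_connections(small_geometry, seed=5)
        b = init_connections(small_geometry, seed=5)
        c = init_connections(small_geometry, seed=6)
        assert np.array_equal(a.signs, b.signs)
        assert np.array_equal(a.magnitudes, b.magnitudes)
        assert not np.array_equal(a.signs, c.signs)

    def test_isolated_neurons_warn(self, small_geometry):
        with pytest.warns(UserWarning, match="no connections"):
            init_connections(small_geometry, radius=0.5, conn_prob=1.0, seed=0)


class TestDynamics:
    def _lonely_neuron_net(self, **kw):
        geom = ReservoirGeometry(
            coords=np.zeros((1, 3)), input_map={"A": 0}, grid_shape=(1, 1, 1)
        )
        return ReservoirNet(
            geometry=geom,
            signs=np.zeros((1, 1), dtype=np.int8),
            magnitudes=np.zeros((1, 1)),
            **kw,
        )

    def test_quiescent_without_input_or_weights(self):
        net = self._lonely_neuron_net()
        rec = run_sample(net, spike_train("A", [], [], 20))
        assert rec.spike_count[0] == 0
        assert rec.first_spike_time[0] == -1

    def test_subthreshold_inputs_accumulate_to_firing(self):
        """Two consecutive +1 events at gain 0.3 cross the 0.5 threshold on the second."""
        net = self._lonely_neuron_net(input_gain=0.3, firing_threshold=0.5, leak=0.0)
        rec = run_sample(net, spike_train("A", [1, 2], [1, 1], 10))
        assert rec.first_spike_time[0] == 2
        assert rec.spike_count[0] == 1

    def test_leak_prevents_slow_accumulation(self):
        net = self._lonely_neuron_net(input_gain=0.3, firing_threshold=0.5, leak=0.9)
        rec = run_sample(net, spike_train("A", [1, 5, 9], [1, 1, 1], 12))
        assert rec.spike_count[0] == 0

    def test_negative_events_cancel_positive_drive(self):
        net = self._lonely_neuron_net(input_gain=0.3, firing_threshold=0.5, leak=0.0)
        rec = run_sample(net, spike_train("A", [1, 2, 3], [1, -1, 1], 10))
        assert rec.spike_count[0] == 0

    def test_refractory_blocks_immediate_refiring(self):
        net = self._lonely_neuron_net(input_gain=1.0, firing_threshold=0.5,
                                      leak=0.0, refractory=3)
        rec = run_sample(net, spike_train("A", [1, 2, 3, 4, 5, 6], [1] * 6, 10))
        assert rec.first_spike_time[0] == 1
        # fires at 1, blocked at 2-4, fires again at 5
        assert rec.spike_count[0] == 2

    def test_raising_threshold_never_adds_spikes(self, small_net):
        rng = np.random.default_rng(0)
        spikes = random_spike_train_set(rng, ("FP1", "C4"), 80, density=0.4)
        counts = []
        for thresh in (0.25, 0.5, 1.0, 2.0):
            net = dataclasses.replace(small_net, firing_threshold=thresh)
            counts.append(run_sample(net, spikes).spike_count)
        for lo, hi in zip(counts[1:], counts[:-1]):
            assert np.all(lo <= hi)

    def test_unknown_spike_channel_rejected(self, small_net):
        spikes = spike_train("Pz", [1], [1], 10)
        with pytest.raises(KeyError, match="Pz"):
            run_sample(small_net, spikes)

    def test_raster_matches_counts(self, small_net):
        rng = np.random.default_rng(1)
        spikes = random_spike_train_set(rng, ("FP1", "C4"), 60, density=0.4)
        rec, raster = run_sample(small_net, spikes, record_dynamics=True)
        from_raster = np.zeros(small_net.n_neurons, dtype=int)
        for fired in raster:
            from_raster[fired] += 1
        assert np.array_equal(from_raster, rec.spike_count)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_propagation_matches_naive_reference(self, small_geometry, seed):
        """Spike times and counts agree exactly with the step-by-step reference."""
        net = init_connections(small_geometry, radius=2.0, conn_prob=0.6,
                               seed=seed, w0=0.4, leak=0.1)
        rng = np.random.default_rng(100 + seed)
        spikes = random_spike_train_set(rng, ("FP1", "C4"), 50, density=0.5)
        rec = run_sample(net, spikes)
        ref_first, ref_counts, _ = reference_simulate(net, spikes)
        assert np.array_equal(rec.first_spike_time, ref_first)
        assert np.array_equal(rec.spike_count, ref_counts)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_stdp_weights_match_naive_reference(self, small_geometry, seed):
        """Post-STDP magnitudes agree bit-for-bit with the reference."""
        net = init_connections(small_geometry, radius=2.0, conn_prob=0.6,
                               seed=seed, w0=0.4, leak=0.1)
        rng = np.random.default_rng(200 + seed)
        spikes = random_spike_train_set(rng, ("FP1", "C4"), 50, density=0.6, signed=False)
        trained = train_stdp(net, [spikes], rate=0.01)
        _, _, ref_mags = reference_simulate(net, spikes, stdp_rate=0.01)
        assert np.array_equal(trained.magnitudes, ref_mags)
        # original net untouched
        assert not np.array_equal(trained.magnitudes, net.magnitudes)


class TestStdp:
    def _two_neuron_net(self, magnitude, **kw):
        geom = ReservoirGeometry(
            coords=np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
            input_map={"A": 0},
            grid_shape=(2, 1, 1),
        )
        signs = np.zeros((2, 2), dtype=np.int8)
        signs[0, 1] = 1
        mags = np.zeros((2, 2))
        mags[0, 1] = magnitude
        return ReservoirNet(geometry=geom, signs=signs, magnitudes=mags,
                            input_gain=1.0, firing_threshold=0.5, leak=0.0,
                            refractory=1, **kw)

    def test_causal_pairings_add_rate_each(self):
        """Pre firing one step before post potentiates by rate per pairing."""
        net = self._two_neuron_net(0.6)
        times = [1, 5, 9, 13]  # neuron 0 fires at each, neuron 1 one step later
        spikes = spike_train("A", times, [1] * 4, 20)
        trained = train_stdp(net, [spikes], rate=0.01)
        assert trained.magnitudes[0, 1] == pytest.approx(0.6 + 4 * 0.01, abs=1e-12)

    def test_potentiation_caps_at_w_cap(self):
        net = self._two_neuron_net(0.995)
        spikes = spike_train("A", [1, 5, 9], [1, 1, 1], 12)
        trained = train_stdp(net, [spikes], rate=0.01)
        assert trained.magnitudes[0, 1] == net.w_cap

    def test_no_spikes_no_change(self, small_net):
        empty = SpikeTrainSet(
            channel_names=("FP1", "C4"),
            times=(np.array([], dtype=np.int64),) * 2,
            polarities=(np.array([], dtype=np.int8),) * 2,
            n_timepoints=40,
        )
        trained = train_stdp(small_net, [empty])
        assert np.array_equal(trained.magnitudes, small_net.magnitudes)

    def test_training_determinism(self, small_net):
        rng = np.random.default_rng(9)
        spikes = [random_spike_train_set(rng, ("FP1", "C4"), 60, 0.4) for _ in range(3)]
        a = train_stdp(small_net, spikes)
        b = train_stdp(small_net, spikes)
        assert np.array_equal(a.magnitudes, b.magnitudes)

    def test_structure_conserved_through_training(self, small_net):
        """Sparsity, signs, locality and magnitude bounds survive STDP."""
        rng = np.random.default_rng(10)
        spikes = [random_spike_train_set(rng, ("FP1", "C4"), 80, 0.5) for _ in range(4)]
        trained = train_stdp(small_net, spikes, rate=0.05)
        assert np.array_equal(trained.signs, small_net.signs)
        assert np.all(trained.magnitudes[trained.signs == 0] == 0)
        pre, post = np.nonzero(trained.magnitudes)
        d = np.linalg.norm(
            trained.geometry.coords[pre] - trained.geometry.coords[post], axis=1
        )
        assert np.all(d <= trained.radius + 1e-12)
        assert np.all(trained.magnitudes >= 0)
        assert np.all(trained.magnitudes <= trained.w_cap)


def test_stimulus_selectivity_after_training():
    """Trained cube states separate two strongly distinct classes (5 seeds)."""
    ratios = []
    for seed in range(5):
        ds = synthetic.generate_dataset(
            1, 12, synthetic.strongly_separated_params(), seed=seed
        )
        spec = io.ExperimentSpec(
            name="sel", participant_indices=(0,), trial_indices=tuple(range(12)),
            window_start_s=2.0, window_len_points=384,
        )
        samples = io.build_samples(ds, spec)
        labels = np.array(samples.labels)
        if len(set(labels)) < 2:
            continue
        encoded = encoding.encode_set(samples)
        geom = build_geometry(125, (5, 5, 5), spec.channels)
        net = train_stdp(init_connections(geom, seed=seed), encoded)
        recs = [run_sample(net, e) for e in encoded]
        f = np.stack([
            np.where(r.first_spike_time < 0, r.duration, r.first_spike_time)
            for r in recs
        ]).astype(float)
        dist = np.linalg.norm(f[:, None, :] - f[None, :, :], axis=2)
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(len(labels), dtype=bool)
        ratios.append(dist[~same].mean() / dist[same & off].mean())
    assert np.mean(ratios) > 1.0


def test_serialization_roundtrip(tmp_path, small_net):
    rng = np.random.default_rng(12)
    spikes = random_spike_train_set(rng, ("FP1", "C4"), 50, 0.4)
    path = tmp_path / "net.npz"
    reservoir.save_reservoir(small_net, path)
    back = reservoir.load_reservoir(path)
    assert back.fingerprint() == small_net.fingerprint()
    assert back.geometry.input_map == small_net.geometry.input_map
    a, b = run_sample(small_net, spikes), run_sample(back, spikes)
    assert np.array_equal(a.first_spike_time, b.first_spike_time)
    assert np.array_equal(a.spike_count, b.spike_count)
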