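"""Participation coefficients, flexibility, and within-module z-scores.

The brute-force oracles here loop explicitly over communities (and, for the
temporal participation coefficient, over every partition time point u),
independently of the vectorized implementations they check.
"""

import numpy as np
import pytest

from tempopc import core, measures, synthetic


def brute_force_pc(net_slice, labels):
    """PC by explicit per-community summation."""
    n = net_slice.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k_i = net_slice[i].sum()
        if k_i == 0:
            continue
        acc = 0.0
        for s in set(labels.tolist()):
            k_is = sum(net_slice[i, j] for j in range(n) if labels[j] == s)
            acc += (k_is / k_i) ** 2
        out[i] = 1.0 - acc
    return out


def brute_force_tpc(weights, labels):
    """TPC by an explicit double loop over (partition time u, community s)."""
    n, _, t_len = weights.shape
    out = np.zeros((n, t_len))
    for i in range(n):
        for t in range(t_len):
            k_it = weights[i, :, t].sum()
            if k_it == 0:
                continue
            acc = 0.0
            for u in range(t_len):
                for s in set(labels[:, u].tolist()):
                    k_its = sum(
                        weights[i, j, t]
                        for j in range(n)
                        if labels[j, u] == s
                    )
                    acc += (k_its / k_it) ** 2
            out[i, t] = 1.0 - acc / t_len
    return out


def equal_split_slice(m, weight=1.0):
    """Star: node 0 connected to m satellites, each its own community."""
    sl = np.zeros((m + 1, m + 1))
    sl[0, 1:] = sl[1:, 0] = weight
    labels = np.arange(m + 1)
    labels[0] = 1  # focal node shares community 1 with the first satellite
    return sl, core.StaticPartition(labels)


class TestStaticPC:
    def test_all_strength_in_own_community_is_zero(self):
        sl = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        part = core.StaticPartition(np.zeros(3, dtype=int))
        np.testing.assert_array_equal(measures.static_pc(sl, part), 0.0)

    @pytest.mark.parametrize("m", range(2, 9))
    def test_equal_split_closed_form(self, m):
        # strength split equally over M communities -> PC = 1 - 1/M exactly
        sl = np.zeros((m + 1, m + 1))
        sl[0, 1:] = sl[1:, 0] = 1.0
        part = core.StaticPartition(np.arange(m + 1))  # each satellite its own
        pc = measures.static_pc(sl, part)
        assert pc[0] == pytest.approx(1.0 - 1.0 / m, abs=1e-15)

    def test_two_weight_levels_matches_oracle(self, rng):
        sl = rng.choice([0.5, 1.0], size=(7, 7))
        sl = np.triu(sl, 1)
        sl = sl + sl.T
        labels = rng.integers(0, 3, size=7)
        got = measures.static_pc(sl, core.StaticPartition(labels))
        np.testing.assert_allclose(got, brute_force_pc(sl, labels), atol=1e-12)

    def test_partition_length_mismatch(self):
        with pytest.raises(core.ValidationError):
            measures.static_pc(np.zeros((3, 3)), core.StaticPartition([0, 1]))

    def test_isolated_node_zero_by_convention(self):
        sl = np.zeros((3, 3))
        sl[1, 2] = sl[2, 1] = 1.0
        pc = measures.static_pc(sl, core.StaticPartition([0, 0, 1]))
        assert pc[0] == 0.0


class TestPCThroughTime:
    def test_constant_network_constant_columns(self, rng):
        sl = rng.uniform(0, 1, size=(5, 5))
        sl = np.triu(sl, 1) + np.triu(sl, 1).T
        net = core.TemporalNetwork(
            np.repeat(sl[:, :, None], 4, axis=2), thresholded=True
        )
        part = core.StaticPartition(rng.integers(0, 2, size=5))
        series = measures.pc_s(net, part)
        for t in range(1, 4):
            np.testing.assert_array_equal(series.values[:, t], series.values[:, 0])

    def test_even_spread_raises_participation(self):
        toy = synthetic.make_toy("fig1b")
        series = measures.pc_s(toy.network, toy.static_partition)
        assert series.values[toy.focal_node, 1] > series.values[toy.focal_node, 0]

    def test_constant_partition_sequence_equals_static(self, small_network, rng):
        labels = rng.integers(0, 3, size=5)
        parts = core.PartitionSequence(np.tile(labels[:, None], (1, 4)))
        a = measures.pc_s(small_network, core.StaticPartition(labels)).values
        b = measures.pc_t(small_network, parts).values
        c = measures.tpc(small_network, parts).values
        np.testing.assert_allclose(a, b, atol=1e-12)
        np.testing.assert_allclose(a, c, atol=1e-12)

    def test_absorption_lowers_per_slice_temporal_pc(self):
        toy = synthetic.make_toy("fig1c")
        series = measures.pc_t(toy.network, toy.planted_partitions)
        assert series.values[toy.focal_node, 1] < series.values[toy.focal_node, 0]

    def test_singleton_partition_closed_form(self):
        m = 5
        sl = np.zeros((m + 1, m + 1))
        sl[0, 1:] = sl[1:, 0] = 0.7
        net = core.TemporalNetwork(sl[:, :, None], thresholded=True)
        parts = core.PartitionSequence(np.arange(m + 1)[:, None])
        series = measures.pc_t(net, parts)
        assert series.values[0, 0] == pytest.approx(1.0 - 1.0 / m, abs=1e-12)

    def test_shape_mismatch_rejected(self, small_network):
        parts = core.PartitionSequence(np.zeros((5, 3), dtype=int))
        with pytest.raises(core.ValidationError, match="match"):
            measures.pc_t(small_network, parts)


class TestTPC:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_double_sum_oracle(self, seed):
        net = synthetic.generate_random_temporal_network(6, 4, 0.7, seed=seed)
        parts = synthetic.generate_random_partition_sequence(6, 4, seed=seed)
        got = measures.tpc(net, parts).values
        np.testing.assert_allclose(
            got, brute_force_tpc(net.weights, parts.labels), atol=1e-12
        )

    def test_two_slice_average_of_contexts(self):
        # T=2: TPC at each slice is the mean of that slice's PC under both
        # partitions -- the averaged-context construction made explicit
        toy = synthetic.make_toy("fig3")
        got = measures.tpc(toy.network, toy.planted_partitions).values
        for t in range(2):
            per_context = [
                measures.static_pc(
                    toy.network.slice(t), toy.planted_partitions.at(u)
                )
                for u in range(2)
            ]
            np.testing.assert_allclose(
                got[:, t], np.mean(per_context, axis=0), atol=1e-12
            )

    def test_uniform_edge_scaling_invariance(self, small_network):
        parts = synthetic.generate_random_partition_sequence(5, 4, seed=3)
        base = measures.tpc(small_network, parts).values
        w = small_network.weights.copy()
        w[2, :, 1] *= 3.0
        w[:, 2, 1] *= 3.0
        scaled = core.TemporalNetwork(w, thresholded=True)
        got = measures.tpc(scaled, parts).values
        np.testing.assert_allclose(got[2, 1], base[2, 1], atol=1e-12)

    def test_column_mean_identity(self, rng):
        # mean over t of TPC equals the mean over t of the u-averaged
        # per-partition PC -- checked against the brute-force oracle means
        net = synthetic.generate_random_temporal_network(5, 5, 0.8, seed=21)
        parts = synthetic.generate_random_partition_sequence(5, 5, seed=21)
        got = measures.tpc(net, parts).values
        oracle = brute_force_tpc(net.weights, parts.labels)
        np.testing.assert_allclose(
            got.mean(axis=1), oracle.mean(axis=1), atol=1e-12
        )

    def test_range_bound(self):
        net = synthetic.generate_random_temporal_network(8, 5, 0.9, seed=2)
        parts = synthetic.generate_random_partition_sequence(8, 5, seed=2)
        vals = measures.tpc(net, parts).values
        assert np.all(vals >= 0) and np.all(vals < 1)


class TestScenarioSignFlips:
    def test_community_split_flips_interpretation(self):
        # the central misinterpretation: per-slice temporal-community PC
        # rises when the community splits through weakened edges, while the
        # static-reference and all-context measures fall
        toy = synthetic.make_toy("fig2_split")
        f = toy.focal_node
        pt = measures.pc_t(toy.network, toy.planted_partitions).values[f]
        ps = measures.pc_s(toy.network, toy.static_partition).values[f]
        tp = measures.tpc(toy.network, toy.planted_partitions).values[f]
        assert pt[1] > pt[0]
        assert ps[1] < ps[0]
        assert tp[1] < tp[0]

    def test_community_extension_flips_interpretation(self):
        toy = synthetic.make_toy("fig2_extend")
        f = toy.focal_node
        pt = measures.pc_t(toy.network, toy.planted_partitions).values[f]
        ps = measures.pc_s(toy.network, toy.static_partition).values[f]
        tp = measures.tpc(toy.network, toy.planted_partitions).values[f]
        assert pt[1] < pt[0]
        assert ps[1] > ps[0]
        assert tp[1] > tp[0]

    def test_unchanged_edges_still_move_temporal_pc(self):
        toy = synthetic.make_toy("fig1d")
        f = toy.focal_node
        np.testing.assert_array_equal(
            toy.network.weights[f, :, 0], toy.network.weights[f, :, 1]
        )
        pt = measures.pc_t(toy.network, toy.planted_partitions).values[f]
        assert pt[1] != pt[0]


class TestFlexibility:
    @pytest.mark.parametrize(
        "sequence, expected",
        [
            ((0, 0, 1, 1, 0), 0.5),
            ((0, 0, 0, 0), 0.0),
            ((0, 1, 0, 1, 0, 1), 1.0),
        ],
    )
    def test_hand_values(self, sequence, expected):
        labels = np.vstack([sequence, np.zeros(len(sequence), dtype=int)])
        flex = measures.flexibility(core.PartitionSequence(labels))
        assert flex[0] == pytest.approx(expected)
        assert flex[1] == 0.0

    def test_single_slice_rejected(self):
        with pytest.raises(core.ValidationError):
            measures.flexibility(core.PartitionSequence(np.zeros((3, 1), dtype=int)))


class TestModuleDegreeZscore:
    def test_equal_strength_community_all_zero(self):
        sl = np.array(
            [[0, 1, 1, 0], [1, 0, 1, 0], [1, 1, 0, 0], [0, 0, 0, 0]], dtype=float
        )
        net = core.TemporalNetwork(sl[:, :, None], thresholded=True)
        z = measures.module_degree_zscore(net, core.StaticPartition([0, 0, 0, 1]))
        np.testing.assert_array_equal(z.values, 0.0)

    def test_hand_computed_three_member_community(self):
        # community {0,1,2}: edges (0,1)=1, (0,2)=2.5, (1,2)=2.5 give
        # within-strengths (3.5, 3.5, 5); the edge (2,3)=3 leaves community B
        # and must not enter node 2's within-strength
        sl = np.array(
            [
                [0.0, 1.0, 2.5, 0.0],
                [1.0, 0.0, 2.5, 0.0],
                [2.5, 2.5, 0.0, 3.0],
                [0.0, 0.0, 3.0, 0.0],
            ]
        )
        net = core.TemporalNetwork(sl[:, :, None], thresholded=True)
        z = measures.module_degree_zscore(net, core.StaticPartition([0, 0, 0, 1]))
        within = np.array([3.5, 3.5, 5.0])
        expected = (within - within.mean()) / within.std()  # population std
        np.testing.assert_allclose(z.values[:3, 0], expected, atol=1e-12)

    def test_singleton_community_zero(self):
        sl = np.zeros((3, 3))
        sl[0, 1] = sl[1, 0] = 1.0
        net = core.TemporalNetwork(sl[:, :, None], thresholded=True)
        z = measures.module_degree_zscore(net, core.StaticPartition([0, 0, 1]))
        assert z.values[2, 0] == 0.0

    def test_temporal_variant_uses_slice_partition(self, small_network):
        parts = synthetic.generate_random_partition_sequence(5, 4, seed=6)
        z_t = measures.module_degree_zscore(small_network, parts)
        assert z_t.measure_name == "z_T"
        # slice t must equal the static z-score computed with partition t
        for t in range(4):
            one = core.TemporalNetwork(
                small_network.weights[:, :, t : t + 1], thresholded=True
            )
            z_static = measures.module_degree_zscore(one, parts.at(t))
            np.testing.assert_allclose(
                z_t.values[:, t], z_static.values[:, 0], atol=1e-12
            )
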