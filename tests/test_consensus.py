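import numpy as np
import pytest

from netmod import (BenchmarkSpec, ModularityConfig, Partition,
                    PartitionEnsemble, WMMConfig, association_matrix,
                    build_partition_pool, filtered_adjacency,
                    generate_weighted_benchmark, louvain_optimize,
                    mean_weight_matrix, nmi, robust_mm, wmm)

from conftest import network_from_edges, partition_from_blocks


class TestAssociationMatrix:
    def test_basic(self):
        part = Partition(["a", "b", "c"], [1, 1, 2])
        T = association_matrix(part)
        assert np.array_equal(T, [[1, 1, 0], [1, 1, 0], [0, 0, 1]])

    def test_one_community_all_ones(self):
        part = Partition(list("abcd"), [3, 3, 3, 3])
        assert np.array_equal(association_matrix(part), np.ones((4, 4)))

    def test_singletons_identity(self):
        part = Partition(list("abcd"), [1, 2, 3, 4])
        assert np.array_equal(association_matrix(part), np.eye(4))

    def test_respects_node_order(self):
        part = Partition(["a", "b", "c"], [1, 1, 2])
        T = association_matrix(part, node_order=["c", "a", "b"])
        assert np.array_equal(T, [[1, 0, 0], [0, 1, 1], [0, 1, 1]])


class TestMeanWeightMatrix:
    def test_two_partition_average(self):
        a = Partition(["a", "b", "c"], [1, 1, 2])  # ab | c
        b = Partition(["a", "b", "c"], [1, 2, 2])  # a | bc
        W = mean_weight_matrix(PartitionEnsemble([a, b]))
        assert W[0, 1] == 0.5 and W[1, 2] == 0.5 and W[0, 2] == 0.0
        assert np.all(np.diag(W) == 1)

    def test_identical_partitions_idempotent(self):
        part = Partition(["a", "b", "c"], [1, 1, 2])
        ens = PartitionEnsemble([part] * 5)
        assert np.array_equal(mean_weight_matrix(ens),
                              association_matrix(part))

    def test_all_ones_and_identity_mix(self):
        ones = Partition(list("abc"), [1, 1, 1])
        single = Partition(list("abc"), [1, 2, 3])
        W = mean_weight_matrix(PartitionEnsemble([ones, single]))
        off = ~np.eye(3, dtype=bool)
        assert np.all(W[off] == 0.5)
        assert np.all(np.diag(W) == 1)

    def test_empty_selection_raises(self):
        part = Partition(["a", "b"], [1, 2])
        with pytest.raises(ValueError, match="empty"):
            mean_weight_matrix(PartitionEnsemble([part]), indices=[])

    def test_bounds_and_symmetry_random(self, rng):
        nodes = [str(i) for i in range(12)]
        parts = [Partition(nodes, rng.integers(0, 4, 12)) for _ in range(9)]
        W = mean_weight_matrix(PartitionEnsemble(parts))
        assert np.all(W >= 0) and np.all(W <= 1)
        assert np.array_equal(W, W.T)


class TestFilteredAdjacency:
    def test_all_ones_identity(self, triangle):
        out = filtered_adjacency(triangle, np.ones((3, 3)))
        assert out == triangle

    def test_identity_filter_annihilates(self, triangle):
        out = filtered_adjacency(triangle, np.eye(3))
        assert out.total_weight == 0

    def test_halved_edge(self, triangle):
        W = np.ones((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        out = filtered_adjacency(triangle, W)
        assert out.weights[0, 1] == 0.5
        assert np.allclose(out.strengths(), [1.5, 1.5, 2.0])

    def test_never_increases_weights(self, rng, bridged_triangles):
        W = rng.random((6, 6))
        W = (W + W.T) / 2
        out = filtered_adjacency(bridged_triangles, W)
        assert np.all(out.weights <= bridged_triangles.weights + 1e-15)

    def test_shape_mismatch(self, triangle):
        with pytest.raises(ValueError, match="shape"):
            filtered_adjacency(triangle, np.ones((4, 4)))


class TestPartitionPool:
    def test_size_one_matches_single_run(self, bridged_triangles):
        cfg = ModularityConfig(seed=5)
        pool = build_partition_pool(bridged_triangles, 1, cfg)
        assert pool.size == 1

    def test_stable_fixture_all_identical(self, bridged_triangles):
        pool = build_partition_pool(bridged_triangles, 10,
                                    ModularityConfig(seed=2))
        W = mean_weight_matrix(pool)
        expected = association_matrix(partition_from_blocks(
            bridged_triangles.node_ids, [["1", "2", "3"], ["4", "5", "6"]]),
            node_order=bridged_triangles.node_ids)
        assert np.array_equal(W, expected)

    def test_noisy_network_has_distinct_partitions(self):
        spec = BenchmarkSpec(n_nodes=60, mean_degree=6, max_degree=12,
                             mu_topology=0.6, mu_weight=0.6, seed=8)
        net, _ = generate_weighted_benchmark(spec)
        pool = build_partition_pool(net, 30, ModularityConfig(seed=3))
        distinct = {tuple(p.aligned_labels(net.node_ids)) for p in pool}
        assert len(distinct) > 1

    def test_pool_deterministic(self, bridged_triangles):
        a = build_partition_pool(bridged_triangles, 5, ModularityConfig(seed=1))
        b = build_partition_pool(bridged_triangles, 5, ModularityConfig(seed=1))
        assert all(x == y for x, y in zip(a, b))


class TestWMM:
    def test_stable_fixture_matches_plain_mm(self, bridged_triangles):
        cfg = WMMConfig(pool_size=10, n_selected=5, n_selections=5, seed=4)
        part, W = wmm(bridged_triangles, cfg, return_weight_matrix=True)
        mm_part = louvain_optimize(bridged_triangles, ModularityConfig(seed=4))
        assert part.equivalent(mm_part)
        expected = association_matrix(partition_from_blocks(
            bridged_triangles.node_ids, [["1", "2", "3"], ["4", "5", "6"]]),
            node_order=bridged_triangles.node_ids)
        assert np.array_equal(W, expected)

    def test_degenerate_l_m_k_one(self, bridged_triangles):
        cfg = WMMConfig(pool_size=1, n_selected=1, n_selections=1, seed=9)
        part = wmm(bridged_triangles, cfg)
        assert part.n_communities == 2

    def test_fixed_point_on_identical_pool(self, two_triangles):
        # strong two-component structure: every stage returns the same split
        cfg = WMMConfig(pool_size=5, n_selected=3, n_selections=3, seed=0)
        part = wmm(two_triangles, cfg)
        assert part.equivalent(partition_from_blocks(
            two_triangles.node_ids, [["1", "2", "3"], ["4", "5", "6"]]))

    def test_deterministic(self, bridged_triangles):
        cfg = WMMConfig(pool_size=6, n_selected=3, n_selections=4, seed=123)
        assert wmm(bridged_triangles, cfg) == wmm(bridged_triangles, cfg)

    def test_beats_or_ties_mm_on_noisy_benchmark(self):
        spec = BenchmarkSpec(n_nodes=100, mean_degree=5, max_degree=25,
                             mu_topology=0.2, mu_weight=0.2, seed=77)
        net, truth = generate_weighted_benchmark(spec)
        runs = 8
        mm_scores, wmm_scores = [], []
        for r in range(runs):
            mm_scores.append(nmi(
                louvain_optimize(net, ModularityConfig(seed=r)), truth))
            wmm_scores.append(nmi(
                wmm(net, WMMConfig(pool_size=15, n_selected=8,
                                   n_selections=8, seed=r)), truth))
        assert np.mean(wmm_scores) >= np.mean(mm_scores) - 1e-12

    def test_edgeless_raises(self):
        net = network_from_edges(3, [])
        with pytest.raises(ValueError, match="edgeless"):
            wmm(net, WMMConfig(pool_size=2, n_selected=1, n_selections=1))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            WMMConfig(pool_size=5, n_selected=10, n_selections=1)


class TestRobustMM:
    def test_recovers_planted_triangles(self, bridged_triangles):
        part = robust_mm(bridged_triangles, pool_size=10, n_null=100,
                         config=ModularityConfig(seed=6))
        assert part.equivalent(partition_from_blocks(
            bridged_triangles.node_ids, [["1", "2", "3"], ["4", "5", "6"]]))

    def test_more_stable_than_mm_on_noisy_benchmark(self):
        from netmod import mean_average_node_entropy
        spec = BenchmarkSpec(n_nodes=60, mean_degree=6, max_degree=12,
                             mu_topology=0.6, mu_weight=0.6, seed=21)
        net, _ = generate_weighted_benchmark(spec)
        mm_parts = [louvain_optimize(net, ModularityConfig(seed=r))
                    for r in range(8)]
        rb_parts = [robust_mm(net, pool_size=15, n_null=60,
                              config=ModularityConfig(seed=r))
                    for r in range(8)]
        h_mm = mean_average_node_entropy(PartitionEnsemble(mm_parts))
        h_rb = mean_average_node_entropy(PartitionEnsemble(rb_parts))
        assert h_rb <= h_mm + 1e-12

    def test_deterministic(self, bridged_triangles):
        a = robust_mm(bridged_triangles, pool_size=8, n_null=50,
                      config=ModularityConfig(seed=3))
        b = robust_mm(bridged_triangles, pool_size=8, n_null=50,
                      config=ModularityConfig(seed=3))
        assert a == b

    def test_pool_size_validation(self, triangle):
        with pytest.raises(ValueError, match="pool_size"):
            robust_mm(triangle, pool_size=1)

    def test_degenerate_one_community_pool(self, triangle):
        # every run puts the triangle in one community; the label-permuted
        # null is saturated too, so the strict tie rule empties the matrix
        # and each node falls back to a singleton
        part = robust_mm(triangle, pool_size=5, n_null=20,
                         config=ModularityConfig(seed=1))
        assert part.n_communities == 3
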