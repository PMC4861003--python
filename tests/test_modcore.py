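import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ripnet import (
    Partition,
    leading_eigenvector_split,
    modularity_matrix,
    modularity_score,
    newman_partition,
    subgroup_modularity_matrix,
)

from .conftest import adjacency_from_edges, random_adjacency
from .oracles import best_bipartition_modularity, modularity_of_labels


class TestModularityMatrix:
    def test_two_triangles_hand_values(self, two_triangles):
        mm = modularity_matrix(two_triangles)
        np.testing.assert_allclose(mm.degrees, 2.0)
        assert mm.m == pytest.approx(6.0)
        np.testing.assert_allclose(mm.B, two_triangles.values - 1.0 / 3.0)

    def test_single_edge_hand_values(self):
        adj = adjacency_from_edges(2, [(0, 1)])
        mm = modularity_matrix(adj)
        np.testing.assert_allclose(mm.B, [[-0.5, 0.5], [0.5, -0.5]])
        assert mm.m == pytest.approx(1.0)

    @given(st.integers(0, 200))
    def test_rows_sum_to_zero(self, seed):
        adj = random_adjacency(np.random.default_rng(seed), 8)
        mm = modularity_matrix(adj)
        np.testing.assert_allclose(mm.B.sum(axis=1), 0.0, atol=1e-8)
        np.testing.assert_allclose(mm.B, mm.B.T, atol=1e-12)

    def test_edgeless_network_raises(self):
        adj = adjacency_from_edges(3, [])
        with pytest.raises(ValueError, match="no edges"):
            modularity_matrix(adj)


class TestModularityScore:
    def test_single_community_is_zero(self, two_triangles, rng):
        ids = two_triangles.gene_ids
        assert modularity_score(two_triangles, Partition(np.zeros(6), ids)) == pytest.approx(
            0.0, abs=1e-12
        )
        for seed in range(5):
            adj = random_adjacency(np.random.default_rng(seed), 9)
            p = Partition(np.zeros(9), adj.gene_ids)
            assert modularity_score(adj, p) == pytest.approx(0.0, abs=1e-12)

    def test_two_triangles_split_is_half(self, two_triangles):
        p = Partition([0, 0, 0, 1, 1, 1], two_triangles.gene_ids)
        assert modularity_score(two_triangles, p) == pytest.approx(0.5, abs=1e-12)

    def test_k4_any_balanced_split_negative(self, k4):
        for labels in ([0, 0, 1, 1], [0, 1, 0, 1], [0, 1, 1, 0]):
            assert modularity_score(k4, Partition(labels, k4.gene_ids)) < 0

    def test_agrees_with_pair_loop_oracle(self, rng):
        for _ in range(10):
            adj = random_adjacency(rng, 10)
            labels = rng.integers(0, 3, size=10)
            q = modularity_score(adj, Partition(labels, adj.gene_ids))
            assert q == pytest.approx(modularity_of_labels(adj.values, labels), abs=1e-10)

    def test_agrees_with_networkx(self, rng):
        import networkx as nx

        for _ in range(5):
            adj = random_adjacency(rng, 12)
            labels = rng.integers(0, 3, size=12)
            q = modularity_score(adj, Partition(labels, adj.gene_ids))
            G = nx.from_numpy_array(adj.values)
            comms = [
                {i for i in range(12) if labels[i] == l} for l in np.unique(labels)
            ]
            assert q == pytest.approx(nx.community.modularity(G, comms), abs=1e-10)


class TestLeadingEigenvectorSplit:
    def test_separates_two_triangles(self, two_triangles):
        mm = modularity_matrix(two_triangles)
        res = leading_eigenvector_split(mm.B, mm.m)
        assert res.is_split
        assert res.deltaQ == pytest.approx(0.5, abs=1e-10)
        assert len(set(res.s[:3])) == 1 and len(set(res.s[3:])) == 1
        assert res.s[0] != res.s[3]

    def test_split_never_beats_exhaustive_maximum(self, rng):
        for _ in range(20):
            adj = random_adjacency(rng, 9)
            mm = modularity_matrix(adj)
            res = leading_eigenvector_split(mm.B, mm.m)
            assert res.deltaQ <= best_bipartition_modularity(adj.values) + 1e-10

    def test_k4_has_no_positive_split(self, k4):
        mm = modularity_matrix(k4)
        res = leading_eigenvector_split(mm.B, mm.m)
        assert (not res.is_split) or res.deltaQ <= 1e-10
        # exhaustive search confirms no bipartition of K4 gains modularity
        assert best_bipartition_modularity(k4.values) <= 1e-10

    def test_single_node_group_degenerate(self):
        res = leading_eigenvector_split(np.zeros((1, 1)), m=1.0)
        assert not res.is_split
        assert res.deltaQ == 0.0

    def test_sign_convention_deterministic(self, rng):
        adj = random_adjacency(rng, 15)
        mm = modularity_matrix(adj)
        r1 = leading_eigenvector_split(mm.B, mm.m)
        r2 = leading_eigenvector_split(mm.B.copy(), mm.m)
        np.testing.assert_array_equal(r1.s, r2.s)


class TestSubgroupMatrix:
    def test_full_group_is_identity_case(self, two_triangles):
        mm = modularity_matrix(two_triangles)
        np.testing.assert_allclose(
            subgroup_modularity_matrix(mm.B, np.arange(6)), mm.B, atol=1e-12
        )

    def test_singleton_group_is_zero(self, two_triangles):
        mm = modularity_matrix(two_triangles)
        np.testing.assert_allclose(subgroup_modularity_matrix(mm.B, [2]), 0.0, atol=1e-12)

    def test_one_triangle_hand_evaluation(self, two_triangles):
        mm = modularity_matrix(two_triangles)
        g = [0, 1, 2]
        expected = mm.B[np.ix_(g, g)].copy()
        expected -= np.diag(expected.sum(axis=1))
        Bg = subgroup_modularity_matrix(mm.B, g)
        np.testing.assert_allclose(Bg, expected, atol=1e-12)
        np.testing.assert_allclose(Bg.sum(axis=1), 0.0, atol=1e-10)

    def test_empty_group_rejected(self, two_triangles):
        mm = modularity_matrix(two_triangles)
        with pytest.raises(ValueError):
            subgroup_modularity_matrix(mm.B, [])


class TestNewmanPartition:
    def test_two_triangles_recovered(self, two_triangles):
        p = newman_partition(two_triangles)
        assert p.n_modules == 2
        assert len(set(p.labels[:3])) == 1 and len(set(p.labels[3:])) == 1

    def test_complete_graph_single_module(self):
        k6 = adjacency_from_edges(6, [(i, j) for i in range(6) for j in range(i + 1, 6)])
        assert newman_partition(k6).n_modules == 1
        assert best_bipartition_modularity(k6.values) <= 1e-10

    def test_two_cliques_with_bridge(self):
        edges = [(i, j) for i in range(10) for j in range(i + 1, 10)]
        edges += [(i + 10, j + 10) for i, j in edges]
        edges.append((0, 10))
        adj = adjacency_from_edges(20, edges)
        p = newman_partition(adj)
        assert p.n_modules == 2
        assert set(p.labels[:10]) != set(p.labels[10:])
        # closed-form community Q for the accepted split
        q = modularity_score(adj, p)
        m = adj.values.sum() / 2
        e_c, d_c = 45, 91  # within-clique edges; clique degree sum (bridge adds 1)
        q_expected = 2 * (e_c / m - (d_c / (2 * m)) ** 2)
        assert q == pytest.approx(q_expected, abs=1e-12)

    def test_deltaQ_additivity(self, rng):
        for _ in range(10):
            adj = random_adjacency(rng, 30, p=0.15)
            p = newman_partition(adj)
            assert modularity_score(adj, p) == pytest.approx(sum(p.split_gains), abs=1e-8)

    def test_partition_q_nonnegative(self, rng):
        for _ in range(10):
            adj = random_adjacency(rng, 20, p=0.2)
            assert modularity_score(adj, newman_partition(adj)) >= -1e-12

    def test_isolated_nodes_become_tagged_singletons(self):
        adj = adjacency_from_edges(5, [(0, 1), (1, 2), (0, 2)])  # nodes 3,4 isolated
        p = newman_partition(adj)
        singles = [l for l, s in p.module_sizes().items() if s == 1]
        assert len(singles) == 2
        assert all(p.module_tags[l] == "isolated" for l in singles)

    def test_invariant_to_node_relabelling(self, rng):
        from ripnet import AdjacencyMatrix
        from ripnet.evaluate import rand_index

        adj = random_adjacency(rng, 25, p=0.15)
        perm = rng.permutation(25)
        permuted = AdjacencyMatrix(
            adj.values[np.ix_(perm, perm)], [adj.gene_ids[i] for i in perm]
        )
        p1 = newman_partition(adj)
        p2 = newman_partition(permuted)
        assert rand_index(p1, p2) == pytest.approx(1.0)
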