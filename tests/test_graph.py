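"""Graph metrics vs. exhaustive brute-force oracles; null-model laws."""

import itertools

import numpy as np
import pytest

from conftest import random_binary_cm
from mibca import graph as graphm
from mibca.types import ConnectivityMatrix


def _cm(values):
    values = np.asarray(values, dtype=float)
    return ConnectivityMatrix(
        values=values, roi_ids=list(range(1, len(values) + 1)),
        weight_kind="binary",
    )


def complete_graph(n):
    vals = np.ones((n, n)) - np.eye(n)
    return _cm(vals)


def oracle_clustering(adj):
    n = len(adj)
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(adj[i])[0]
        k = len(nbrs)
        if k < 2:
            continue
        t = sum(
            adj[a, b] for a, b in itertools.combinations(nbrs, 2)
        )
        out[i] = 2 * t / (k * (k - 1))
    return out


def oracle_path_length(adj):
    """Floyd-Warshall over the binary adjacency."""
    n = len(adj)
    dist = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        dist = np.minimum(dist, dist[:, k, None] + dist[None, k, :])
    off = dist[~np.eye(n, dtype=bool)]
    finite = off[np.isfinite(off)]
    L = finite.mean() if len(finite) else np.inf
    return L, 1 - len(finite) / len(off)


class TestDegreeClusteringPath:
    def test_complete_graph_closed_forms(self):
        cm = complete_graph(5)
        deg, mean_deg = graphm.degree(cm)
        np.testing.assert_array_equal(deg, 4)
        cc, mean_cc = graphm.clustering_coefficient(cm)
        np.testing.assert_allclose(cc, 1.0)
        L, unreach = graphm.characteristic_path_length(cm)
        assert L == pytest.approx(1.0) and unreach == 0

    def test_empty_graph(self):
        cm = _cm(np.zeros((4, 4)))
        deg, _ = graphm.degree(cm)
        np.testing.assert_array_equal(deg, 0)

    def test_star_graph_clustering_zero(self):
        vals = np.zeros((5, 5))
        vals[0, 1:] = vals[1:, 0] = 1
        cc, _ = graphm.clustering_coefficient(_cm(vals))
        np.testing.assert_allclose(cc, 0.0)

    def test_path_graph_length(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = vals[1, 2] = vals[2, 1] = 1
        L, _ = graphm.characteristic_path_length(_cm(vals))
        assert L == pytest.approx(4 / 3)

    @pytest.mark.parametrize("trial", range(20))
    def test_random_graphs_match_bruteforce(self, rng, trial):
        n = int(rng.integers(4, 16))
        cm = random_binary_cm(rng, n=n, p=float(rng.uniform(0.1, 0.7)))
        adj = cm.values
        deg, _ = graphm.degree(cm)
        np.testing.assert_array_equal(deg, adj.sum(axis=1))
        cc, _ = graphm.clustering_coefficient(cm)
        np.testing.assert_allclose(cc, oracle_clustering(adj), atol=1e-12)
        L, unreach = graphm.characteristic_path_length(cm)
        L_o, unreach_o = oracle_path_length(adj)
        assert L == pytest.approx(L_o)
        assert unreach == pytest.approx(unreach_o)

    def test_directed_input_rejected(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = 1
        cm = ConnectivityMatrix(values=vals, roi_ids=[1, 2, 3], directed=True,
                                weight_kind="binary")
        with pytest.raises(ValueError, match="undirected"):
            graphm.degree(cm)
        indeg, outdeg = graphm.in_out_degree(cm)
        assert outdeg[0] == 1 and indeg[1] == 1

    def test_permutation_equivariance(self, rng):
        cm = random_binary_cm(rng, n=8, p=0.4)
        perm = rng.permutation(8)
        permuted = ConnectivityMatrix(
            values=cm.values[np.ix_(perm, perm)],
            roi_ids=[cm.roi_ids[i] for i in perm], weight_kind="binary",
        )
        deg_a, _ = graphm.degree(cm)
        deg_b, _ = graphm.degree(permuted)
        np.testing.assert_array_equal(deg_b, deg_a[perm])
        cc_a, _ = graphm.clustering_coefficient(cm)
        cc_b, _ = graphm.clustering_coefficient(permuted)
        np.testing.assert_allclose(cc_b, cc_a[perm])


class TestRandomNull:
    def test_edge_count_and_symmetry_preserved(self, rng):
        cm = random_binary_cm(rng, n=10, p=0.3)
        m = cm.values.sum() / 2
        for null in graphm.random_null(cm, n=10, seed=1):
            assert null.values.sum() / 2 == m
            np.testing.assert_array_equal(null.values, null.values.T)
            assert np.all(np.diag(null.values) == 0)

    def test_seed_determinism(self, rng):
        cm = random_binary_cm(rng, n=8, p=0.4)
        a = graphm.random_null(cm, n=3, seed=9)
        b = graphm.random_null(cm, n=3, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.values, y.values)

    def test_edge_placement_uniform_over_pairs(self, rng):
        cm = random_binary_cm(rng, n=8, p=0.3)
        m = int(cm.values.sum() / 2)
        n_null = 2000
        freq = np.zeros((8, 8))
        for null in graphm.random_null(cm, n=n_null, seed=4):
            freq += null.values
        iu = np.triu_indices(8, 1)
        p_edge = m / len(iu[0])
        counts = freq[iu]
        # binomial CI on each pair's edge frequency
        sd = np.sqrt(n_null * p_edge * (1 - p_edge))
        assert np.all(np.abs(counts - n_null * p_edge) < 5 * sd)

    def test_degree_sequence_mode_preserves_degrees(self, rng):
        cm = random_binary_cm(rng, n=10, p=0.4)
        deg, _ = graphm.degree(cm)
        for null in graphm.random_null(
            cm, n=3, seed=2, preserve_degree_sequence=True
        ):
            null_deg, _ = graphm.degree(null)
            np.testing.assert_array_equal(np.sort(null_deg), np.sort(deg))

    def test_zero_nulls_rejected(self, rng):
        with pytest.raises(ValueError):
            graphm.random_null(random_binary_cm(rng), n=0)


class TestSmallWorldness:
    def test_ring_lattice_high_normalized_clustering(self):
        n, k = 20, 4
        vals = np.zeros((n, n))
        for i in range(n):
            for d in range(1, k // 2 + 1):
                j = (i + d) % n
                vals[i, j] = vals[j, i] = 1
        rep = graphm.small_worldness(_cm(vals), n_null=10, seed=0)
        assert rep.normalized["clustering"] > 1.5

    def test_seed_determinism(self, rng):
        cm = random_binary_cm(rng, n=12, p=0.4)
        a = graphm.small_worldness(cm, seed=3)
        b = graphm.small_worldness(cm, seed=3)
        assert a.sigma == b.sigma


class TestModularity:
    @staticmethod
    def two_cliques(k=4):
        n = 2 * k
        vals = np.zeros((n, n))
        for block in (range(k), range(k, n)):
            for i, j in itertools.combinations(block, 2):
                vals[i, j] = vals[j, i] = 1
        return _cm(vals)

    def exhaustive_best_q(self, cm):
        """Search all partitions (Bell number) for the maximal Q."""
        n = cm.n_rois
        best_q, best_p = -1.0, None
        def partitions(elements):
            if not elements:
                yield []
                return
            head, *rest = elements
            for smaller in partitions(rest):
                for i, block in enumerate(smaller):
                    yield smaller[:i] + [[head] + block] + smaller[i + 1:]
                yield [[head]] + smaller
        for part in partitions(list(range(n))):
            mapping = {}
            for ci, block in enumerate(part):
                for node in block:
                    mapping[node] = ci
            q = graphm.modularity_q(cm, mapping)
            if q > best_q:
                best_q, best_p = q, part
        return best_q, best_p

    def test_two_disjoint_4cliques_optimal(self):
        cm = self.two_cliques(4)
        partition, q = graphm.modularity(cm, seed=0)
        assert q == pytest.approx(0.5)
        # the partition is exactly the two cliques
        groups = {}
        for node, c in partition.items():
            groups.setdefault(c, set()).add(node)
        assert sorted(map(sorted, groups.values())) == [
            [0, 1, 2, 3], [4, 5, 6, 7]
        ]
        best_q, _ = self.exhaustive_best_q(cm)
        assert q == pytest.approx(best_q)

    def test_complete_graph_trivial_partition(self):
        cm = complete_graph(5)
        partition, q = graphm.modularity(cm, seed=0)
        assert q == pytest.approx(0.0, abs=1e-9)
        assert len(set(partition.values())) == 1

    def test_returned_q_matches_formula(self, rng):
        cm = random_binary_cm(rng, n=9, p=0.35)
        partition, q = graphm.modularity(cm, seed=1)
        assert q == pytest.approx(graphm.modularity_q(cm, partition))

    def test_louvain_never_beats_exhaustive_on_small_graphs(self, rng):
        for _ in range(5):
            cm = random_binary_cm(rng, n=6, p=0.5)
            if cm.values.sum() == 0:
                continue
            _, q = graphm.modularity(cm, seed=0)
            best_q, _ = self.exhaustive_best_q(cm)
            assert q <= best_q + 1e-9

    def test_negative_weights_rejected(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = -1
        cm = ConnectivityMatrix(values=vals, roi_ids=[1, 2, 3],
                                weight_kind="count")
        with pytest.raises(ValueError, match="nonnegative"):
            graphm.modularity(cm)
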