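"""Graph-theory measures against closed forms, brute force and networkx."""

import itertools

import networkx as nx
import numpy as np
import pytest

from neogenet import (
    BinaryNetwork,
    classify_edges,
    global_measures,
    local_measures,
    rewire_preserving_degree,
    rich_club,
)
from neogenet.metrics import (
    betweenness_centrality,
    characteristic_path_length,
    global_efficiency,
    local_efficiency,
    modularity_spectral,
    rich_club_coefficients,
)
from neogenet._matrixops import matching_matrix
from conftest import random_adjacency


def _dist(n, rng=None):
    rng = rng or np.random.default_rng(0)
    pts = rng.random((n, 3)) * 50
    from scipy.spatial.distance import pdist, squareform
    return squareform(pdist(pts))


def _adj(edges, n):
    a = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return a


class TestClosedForms:
    def test_complete_graph_k4(self):
        a = 1 - np.eye(4, dtype=np.uint8)
        lm = local_measures(a, _dist(4))
        assert np.all(lm.clustering == 1.0)
        assert np.all(lm.betweenness == 0.0)
        assert np.all(lm.degree == 3)

    def test_path_graph_betweenness_and_degree(self):
        """a-b-c: b carries the single a-c geodesic."""
        a = _adj([(0, 1), (1, 2)], 3)
        lm = local_measures(a, _dist(3))
        assert list(lm.degree) == [1, 2, 1]
        assert np.allclose(lm.betweenness, [0.0, 1.0, 0.0])

    def test_matching_identical_neighbourhoods(self):
        # nodes 0 and 1 both connect to {2, 3} and not to each other
        a = _adj([(0, 2), (0, 3), (1, 2), (1, 3)], 4)
        m = matching_matrix(a.astype(float))
        assert m[0, 1] == 1.0

    def test_ring6_path_length(self):
        a = _adj([(i, (i + 1) % 6) for i in range(6)], 6)
        assert characteristic_path_length(a) == pytest.approx(1.8)

    def test_complete_graph_global(self):
        a = 1 - np.eye(5, dtype=np.uint8)
        gm = global_measures(a, _dist(5))
        assert gm.global_efficiency == pytest.approx(1.0)
        assert gm.characteristic_path_length == pytest.approx(1.0)
        assert gm.modularity_q == pytest.approx(0.0, abs=1e-12)
        assert len(np.unique(gm.partition)) == 1

    def test_two_triangles_modularity(self):
        """Two disjoint K3s: Q of the natural bipartition is 1/2."""
        a = _adj([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)], 6)
        q, labels = modularity_spectral(a)
        assert q == pytest.approx(0.5)
        assert len(np.unique(labels)) == 2
        assert len(np.unique(labels[:3])) == 1 and len(np.unique(labels[3:])) == 1

    def test_empty_network(self):
        a = np.zeros((5, 5), dtype=np.uint8)
        gm = global_measures(a, _dist(5))
        assert gm.global_efficiency == 0.0
        assert np.isnan(gm.characteristic_path_length)
        assert gm.modularity_q == 0.0


def _brute_q(a, labels):
    """Modularity from its definition."""
    two_m = a.sum()
    k = a.sum(axis=1)
    q = 0.0
    n = a.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += a[i, j] - k[i] * k[j] / two_m
    return q / two_m


def _brute_matching(a):
    n = a.shape[0]
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ni = set(np.flatnonzero(a[i])) - {j}
            nj = set(np.flatnonzero(a[j])) - {i}
            union = ni | nj
            m[i, j] = len(ni & nj) / len(union) if union else 0.0
    return m


def _brute_rich_club(a):
    deg = a.sum(axis=1)
    out = {}
    for k in range(1, int(deg.max())):
        nodes = np.flatnonzero(deg > k)
        if len(nodes) < 2:
            continue
        e = sum(a[i, j] for i, j in itertools.combinations(nodes, 2))
        out[k] = 2 * e / (len(nodes) * (len(nodes) - 1))
    return out


class TestOracleEquivalence:
    """Every measure vs networkx / brute force on small random graphs."""

    @pytest.mark.parametrize("trial", range(25))
    def test_measures_match_oracles(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(4, 9))
        a = random_adjacency(n, rng.uniform(0.25, 0.85), rng).astype(float)
        d = _dist(n, rng)
        g = nx.from_numpy_array(a)
        lm = local_measures(a, d)

        assert np.array_equal(lm.degree, [g.degree(i) for i in range(n)])
        nx_clu = nx.clustering(g)
        assert np.allclose(lm.clustering, [nx_clu[i] for i in range(n)])
        nx_btw = nx.betweenness_centrality(g, normalized=False)
        assert np.allclose(lm.betweenness, [nx_btw[i] for i in range(n)])
        assert np.allclose(lm.nodal_edge_length, (a * d).sum(axis=1))
        assert np.allclose(lm.matching, _brute_matching(a).sum(axis=1) / (n - 1))

        # local efficiency: networkx's definition matches the neighbourhood
        # subgraph efficiency used here
        assert np.allclose(
            local_efficiency(a),
            [nx.global_efficiency(g.subgraph(list(g[i]))) for i in range(n)],
        )
        assert global_efficiency(a) == pytest.approx(nx.global_efficiency(g))

        # characteristic path length: mean over connected pairs
        finite = [
            l
            for _, targets in nx.all_pairs_shortest_path_length(g)
            for t, l in targets.items()
            if l > 0
        ]
        if finite:
            assert characteristic_path_length(a) == pytest.approx(np.mean(finite))

        # modularity: Q of the returned partition evaluated independently
        q, labels = modularity_spectral(a)
        if a.sum() > 0:
            assert q == pytest.approx(_brute_q(a, labels))
            # and at least as good as the trivial partition
            assert q >= -1e-12

        # rich club
        ks, phi = rich_club_coefficients(a)
        brute = _brute_rich_club(a)
        assert list(ks) == sorted(brute)
        for k, p in zip(ks, phi):
            assert p == pytest.approx(brute[k])

    def test_modularity_not_worse_than_greedy(self):
        """Sanity on a modular planted graph: spectral Q >= 90% of the
        networkx greedy-modularity Q."""
        rng = np.random.default_rng(5)
        blocks = [range(0, 8), range(8, 16), range(16, 24)]
        a = np.zeros((24, 24))
        for b in blocks:
            for i, j in itertools.combinations(b, 2):
                if rng.random() < 0.7:
                    a[i, j] = a[j, i] = 1
        for i, j in itertools.combinations(range(24), 2):
            if a[i, j] == 0 and rng.random() < 0.03:
                a[i, j] = a[j, i] = 1
        q, _ = modularity_spectral(a)
        g = nx.from_numpy_array(a)
        comms = nx.community.greedy_modularity_communities(g)
        q_ref = nx.community.modularity(g, comms)
        assert q >= 0.9 * q_ref


class TestRewiring:
    def test_degree_sequence_preserved(self):
        rng = np.random.default_rng(0)
        a = random_adjacency(20, 0.3, rng)
        for _ in range(5):
            null = rewire_preserving_degree(a, 10, rng)
            assert np.array_equal(null.degree, a.sum(axis=1))
            assert null.n_edges * 2 == a.sum()
            assert np.all(np.diag(null.adjacency) == 0)

    def test_star_graph_unchanged(self):
        """K1,3 admits no valid double-edge swap."""
        a = _adj([(0, 1), (0, 2), (0, 3)], 4)
        null = rewire_preserving_degree(a, 10, np.random.default_rng(1))
        assert np.array_equal(null.adjacency, a)

    def test_actually_randomises(self):
        rng = np.random.default_rng(3)
        a = random_adjacency(20, 0.3, rng)
        null = rewire_preserving_degree(a, 10, rng)
        assert not np.array_equal(null.adjacency, a)


class TestRichClub:
    def test_complete_graph_phi_one(self):
        a = (1 - np.eye(6)).astype(np.uint8)
        ks, phi = rich_club_coefficients(a)
        assert np.all(phi == 1.0)
        rc = rich_club(a, n_nulls=20, rng=np.random.default_rng(0))
        assert np.allclose(rc.phi_norm, 1.0)
        # nulls are identical, so nothing is significantly above chance
        assert rc.k_star is None

    def test_planted_hub_clique_recovered(self):
        """20 nodes; a 3-clique of degree-5 hubs over a degree-3/4 periphery:
        the hub trio is recovered as the rich club at the significant k.

        The periphery must be dense enough that degree-preserving nulls
        rarely reproduce the full hub triangle, otherwise the clique is
        forced by the degree sequence and nothing is above chance.
        """
        hubs = [0, 1, 2]
        hub_edges = [(0, 1), (0, 2), (1, 2)]
        spokes = [(0, 3), (0, 4), (0, 5), (1, 6), (1, 7), (1, 8), (2, 9), (2, 10), (2, 11)]
        ring = [(i, i + 1) for i in range(3, 19)] + [(19, 3)]
        chords = [(3, 12), (5, 14), (7, 16), (9, 18), (11, 13),
                  (15, 19), (4, 17), (6, 18), (8, 13), (10, 16)]
        a = _adj(hub_edges + spokes + ring + chords, 20)
        rc = rich_club(a, n_nulls=500, rng=np.random.default_rng(4))
        assert rc.k_star is not None
        assert set(rc.rich_nodes) == set(hubs)
        # brute-force check of the raw coefficient at the selected level
        deg = a.sum(axis=1)
        nodes = np.flatnonzero(deg > rc.k_star)
        e = a[np.ix_(nodes, nodes)].sum() / 2
        phi_expected = 2 * e / (len(nodes) * (len(nodes) - 1))
        assert rc.phi[list(rc.k_levels).index(rc.k_star)] == pytest.approx(phi_expected)

    def test_null_degree_sequences_exact(self):
        rng = np.random.default_rng(9)
        a = random_adjacency(15, 0.4, rng)
        deg = a.sum(axis=1)
        for _ in range(10):
            null = rewire_preserving_degree(a, 10, rng)
            assert np.array_equal(null.degree, deg)


class TestEdgeClasses:
    def test_empty_and_full_rich_sets(self):
        a = random_adjacency(10, 0.4, np.random.default_rng(2))
        d = _dist(10)
        all_local = classify_edges(a, [], d)
        assert all_local.counts["local"] == a.sum() // 2
        assert all_local.counts["rich"] == all_local.counts["feeder"] == 0
        assert np.isnan(all_local.mean_lengths["rich"])
        all_rich = classify_edges(a, range(10), d)
        assert all_rich.counts["rich"] == a.sum() // 2

    def test_three_class_toy(self):
        """rich={a,b}; edges ab (rich), ac (feeder), cd (local)."""
        a = _adj([(0, 1), (0, 2), (2, 3)], 4)
        d = _dist(4)
        cls = classify_edges(a, [0, 1], d)
        assert cls.counts == {"rich": 1, "feeder": 1, "local": 1}
        assert cls.mean_lengths["rich"] == pytest.approx(d[0, 1])
        assert cls.mean_lengths["feeder"] == pytest.approx(d[0, 2])
        assert cls.mean_lengths["local"] == pytest.approx(d[2, 3])

    def test_partition_is_exhaustive(self):
        rng = np.random.default_rng(8)
        a = random_adjacency(12, 0.5, rng)
        cls = classify_edges(a, [0, 3, 7], _dist(12))
        assert sum(cls.counts.values()) == a.sum() // 2


class TestMonotonicity:
    def test_adding_edges_never_decreases_efficiency(self):
        rng = np.random.default_rng(6)
        a = random_adjacency(12, 0.2, rng)
        eff = global_efficiency(a)
        iu = np.triu_indices(12, 1)
        absent = [(i, j) for i, j in zip(*iu) if a[i, j] == 0]
        for idx in rng.permutation(len(absent))[:20]:
            i, j = absent[idx]
            a2 = a.copy()
            a2[i, j] = a2[j, i] = 1
            eff2 = global_efficiency(a2)
            assert eff2 >= eff - 1e-12
            a, eff = a2, eff2


class TestEdgeClassesInGlobal:
    def test_global_measures_include_classes(self, geometry30):
        a = random_adjacency(30, 0.2, np.random.default_rng(3))
        gm = global_measures(
            BinaryNetwork(a, geometry=geometry30), rich_nodes=[0, 1, 2]
        )
        assert gm.n_rich + gm.n_feeder + gm.n_local == a.sum() // 2
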