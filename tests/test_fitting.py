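"""Energy, grids, fingerprints, spatial embedding, grid-search fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ks_2samp

from neogenet import (
    BinaryNetwork,
    GNMSpec,
    energy,
    fit_network,
    grow_network,
    ks_statistic,
    local_measures,
    make_grid,
    spatial_embedding,
    tf_dissimilarity,
    topological_fingerprint,
)
from neogenet.fitting import grid_point_rng, cohort_spatial_embedding
from conftest import random_adjacency


class TestKS:
    def test_identical_samples(self):
        assert ks_statistic([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports(self):
        assert ks_statistic([0, 0], [1, 1]) == 1.0

    def test_hand_enumerated_offset(self):
        """{1,2,3} vs {2,3,4}: ECDFs differ by 1/3 everywhere."""
        assert ks_statistic([1, 2, 3], [2, 3, 4]) == pytest.approx(1 / 3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_statistic([], [1.0])

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            a = rng.normal(size=rng.integers(3, 40))
            b = rng.normal(loc=rng.uniform(-1, 1), size=rng.integers(3, 40))
            assert ks_statistic(a, b) == pytest.approx(ks_2samp(a, b).statistic)


class TestEnergy:
    def test_identity_is_zero(self, geometry30):
        a = random_adjacency(30, 0.2, np.random.default_rng(1))
        e = energy(a, a, geometry30.distance_matrix)
        assert e.energy == 0.0

    def test_empty_vs_complete_is_one(self, geometry30):
        n = 30
        empty = np.zeros((n, n), dtype=np.uint8)
        full = 1 - np.eye(n, dtype=np.uint8)
        e = energy(empty, full, geometry30.distance_matrix)
        assert e.energy == 1.0

    def test_energy_is_max_of_components(self, geometry30):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = random_adjacency(30, 0.15, rng)
            b = random_adjacency(30, 0.15, rng)
            e = energy(a, b, geometry30.distance_matrix)
            assert e.energy == max(e.components)
            assert e.energy in e.components
            assert all(0 <= c <= 1 for c in e.components)

    def test_mismatched_nodes_rejected(self, geometry30):
        with pytest.raises(ValueError, match="node set"):
            energy(np.zeros((4, 4)), np.zeros((5, 5)), geometry30.distance_matrix)

    def test_edge_mode_uses_per_edge_lengths(self, geometry30):
        a = random_adjacency(30, 0.2, np.random.default_rng(3))
        b = random_adjacency(30, 0.2, np.random.default_rng(4))
        e_nodal = energy(a, b, geometry30.distance_matrix, edge_length_mode="nodal")
        e_edge = energy(a, b, geometry30.distance_matrix, edge_length_mode="edge")
        # same degree/clustering/betweenness components, different length one
        assert e_nodal.ks_degree == e_edge.ks_degree
        assert e_nodal.ks_edge_length != e_edge.ks_edge_length


class TestGrid:
    def test_narrow_grid_100x100(self):
        g = make_grid((-3, 0), (0.1, 0.6), 100, 100)
        assert g.n_points == 10_000
        pts = g.points()
        assert pts.shape == (10_000, 2)
        assert [pts[0, 0], pts[0, 1]] == [-3.0, 0.1]
        assert [pts[-1, 0], pts[-1, 1]] == [0.0, 0.6]

    def test_single_point_is_midpoint(self):
        g = make_grid((-3, 0), (0.1, 0.6), 1, 1)
        assert g.points().tolist() == [[-1.5, pytest.approx(0.35)]]

    def test_uniform_spacing(self):
        g = make_grid((-8, 0), (-8, 8), 7, 9)
        assert np.allclose(np.diff(g.eta_values), g.eta_step)
        assert np.allclose(np.diff(g.gamma_values), g.gamma_step)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            make_grid((0, 0), (0.1, 0.6), 5, 5)


class TestFingerprint:
    def test_diagonal_symmetry_and_range(self, geometry30):
        a = random_adjacency(30, 0.25, np.random.default_rng(5))
        tf = topological_fingerprint(a, geometry30.distance_matrix)
        assert tf.shape == (6, 6)
        assert np.allclose(np.diag(tf), 1.0)
        assert np.allclose(tf, tf.T)
        assert np.all((tf >= -1 - 1e-12) & (tf <= 1 + 1e-12))

    def test_regular_ring_zero_variance_convention(self, geometry30):
        """In a ring every degree is 2: degree correlations are set to 0."""
        n = 30
        a = np.zeros((n, n), dtype=np.uint8)
        for i in range(n):
            a[i, (i + 1) % n] = a[(i + 1) % n, i] = 1
        tf = topological_fingerprint(a, geometry30.distance_matrix)
        assert np.all(tf[0, 1:] == 0.0)  # degree row, off-diagonal
        assert tf[0, 0] == 1.0

    def test_dissimilarity_identity_and_hand_value(self):
        tf = np.eye(6)
        assert tf_dissimilarity(tf, tf) == 0.0
        tf2 = tf.copy()
        tf2[0, 1] = tf2[1, 0] = 0.5
        # two symmetric entries differing by 0.5: sqrt(2 * 0.25) = 0.7071
        assert tf_dissimilarity(tf, tf2) == pytest.approx(np.sqrt(0.5))
        with pytest.raises(ValueError):
            tf_dissimilarity(np.eye(6), np.eye(5))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_dissimilarity_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        def rand_tf():
            x = rng.uniform(-1, 1, size=(6, 6))
            x = (x + x.T) / 2
            np.fill_diagonal(x, 1.0)
            return x
        a, b, c = rand_tf(), rand_tf(), rand_tf()
        assert tf_dissimilarity(a, c) <= tf_dissimilarity(a, b) + tf_dissimilarity(b, c) + 1e-12


class TestSpatialEmbedding:
    def test_self_embedding_is_one(self, geometry30):
        a = random_adjacency(30, 0.25, np.random.default_rng(6))
        lm = local_measures(a, geometry30.distance_matrix)
        se = spatial_embedding(lm, lm)
        for name, r in se.items():
            assert r == pytest.approx(1.0)

    def test_permuted_embedding_near_zero(self, geometry30):
        """Node permutation breaks the spatial correspondence: correlations
        average to ~0 across many permutations."""
        a = random_adjacency(30, 0.25, np.random.default_rng(7))
        d = geometry30.distance_matrix
        lm = local_measures(a, d)
        rng = np.random.default_rng(8)
        rs = []
        for _ in range(50):
            perm = rng.permutation(30)
            perm_lm = local_measures(a[np.ix_(perm, perm)], d)
            rs.append(spatial_embedding(lm, perm_lm)["degree"])
        assert abs(np.mean(rs)) < 0.1

    def test_cohort_summary_schema(self):
        per_subject = [
            {m: 0.5 for m in ("degree", "clustering", "betweenness",
                              "nodal_edge_length", "local_efficiency", "matching")}
            for _ in range(5)
        ]
        df = cohort_spatial_embedding(per_subject, n_boot=50,
                                      rng=np.random.default_rng(0))
        assert len(df) == 6
        assert set(df.columns) == {"measure", "mean_r", "ci_lo", "ci_hi", "n"}
        assert np.allclose(df.mean_r, 0.5)


class TestFitNetwork:
    def test_self_fit_recovers_exact_grid_point(self, geometry30):
        """Observed network generated by the engine at a grid point with the
        matched rng stream: that point reproduces it exactly, so E = 0 there
        and the best fit lands on the true parameters."""
        d = geometry30.distance_matrix
        grid = make_grid((-2, -1), (0.2, 0.4), 3, 3)
        pts = grid.points()
        true_idx = 4  # centre of the 3x3 grid
        eta, gamma = pts[true_idx]
        seed_net = np.zeros((30, 30), dtype=np.uint8)
        spec = GNMSpec("matching", float(eta), float(gamma))
        observed = grow_network(seed_net, d, spec, 45,
                                grid_point_rng(123, true_idx)).adjacency
        fr = fit_network(observed, seed_net, d, rule="matching", grid=grid, seed=123)
        assert fr.best_index == true_idx
        assert fr.best_energy == 0.0
        assert (fr.best_eta, fr.best_gamma) == (eta, gamma)

    def test_landscape_bookkeeping(self, geometry30):
        d = geometry30.distance_matrix
        observed = random_adjacency(30, 0.12, np.random.default_rng(10))
        seed_net = np.zeros((30, 30), dtype=np.uint8)
        grid = make_grid((-2, 0), (0.1, 0.5), 3, 3)
        fr = fit_network(observed, seed_net, d, grid=grid, seed=5)
        assert len(fr.landscape) == 9
        assert fr.best_energy == fr.landscape.energy.min()
        assert fr.best_network.n_edges == BinaryNetwork(observed).n_edges
        # ks components bounded and energy is their max at the best row
        row = fr.landscape.loc[fr.best_index]
        assert row.energy == pytest.approx(
            max(row.ks_degree, row.ks_clustering, row.ks_betweenness, row.ks_edge_length)
        )

    def test_landscape_is_smooth(self, geometry30):
        """Energies at neighbouring grid points correlate positively: each
        point's energy tracks the mean of its lattice neighbours (guards
        against rng-stream bugs that would decorrelate the landscape)."""
        d = geometry30.distance_matrix
        truth = GNMSpec("matching", -1.5, 0.3)
        seed_net = np.zeros((30, 30), dtype=np.uint8)
        observed = grow_network(seed_net, d, truth, 60, np.random.default_rng(3)).adjacency
        n_eta = n_gamma = 8
        fr = fit_network(observed, seed_net, d, grid=make_grid((-3, 0), (0.1, 0.8), n_eta, n_gamma),
                         seed=11)
        e = fr.landscape.energy.to_numpy().reshape(n_eta, n_gamma)
        own, nbr = [], []
        for i in range(n_eta):
            for j in range(n_gamma):
                neigh = [e[x, y] for x, y in ((i-1, j), (i+1, j), (i, j-1), (i, j+1))
                         if 0 <= x < n_eta and 0 <= y < n_gamma]
                own.append(e[i, j])
                nbr.append(np.mean(neigh))
        assert np.corrcoef(own, nbr)[0, 1] > 0.3

    def test_seed_larger_than_observed_rejected(self, geometry30):
        d = geometry30.distance_matrix
        observed = np.zeros((30, 30), dtype=np.uint8)
        observed[0, 1] = observed[1, 0] = 1
        seed_net = random_adjacency(30, 0.3, np.random.default_rng(2))
        with pytest.raises(ValueError, match="fewer edges"):
            fit_network(observed, seed_net, d, grid=make_grid(n_eta=2, n_gamma=2))
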