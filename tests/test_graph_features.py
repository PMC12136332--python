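"""Weighted clustering coefficients and symmetric adjacency normalization."""

import numpy as np
import pytest

from dynfcnet.dynfc import DynamicFC
from dynfcnet.graph_features import (
    build_graph_sequence,
    clustering_coefficients,
    local_clustering,
    node_feature_sequence,
    normalize_adjacency,
)
from tests.conftest import random_symmetric_fc


def brute_force_clustering(adj, i):
    """Independent triple-enumeration oracle for the triangle-intensity
    weighted clustering coefficient (weights max-normalized, |.| applied)."""
    w = np.abs(np.array(adj, dtype=float))
    np.fill_diagonal(w, 0.0)
    if w.max() > 0:
        w = w / w.max()
    neigh = [j for j in range(w.shape[0]) if w[i, j] > 0]
    k = len(neigh)
    if k < 2:
        return 0.0
    total = 0.0
    for a in range(k):
        for b in range(a + 1, k):
            j, h = neigh[a], neigh[b]
            if w[j, h] > 0:
                total += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
    return 2.0 * total / (k * (k - 1))


def random_sparse_sym(rng, R, density=0.4, signed=False):
    m = rng.uniform(-1 if signed else 0.05, 1.0, size=(R, R))
    m *= rng.random((R, R)) < density
    m = np.triu(m, 1)
    m = m + m.T
    return m


class TestClustering:
    def test_complete_triangle_all_ones(self):
        adj = np.array([[0, 0.7, 0.7], [0.7, 0, 0.7], [0.7, 0.7, 0]])
        for i in range(3):
            assert local_clustering(adj, i) == pytest.approx(1.0)

    def test_star_graph_is_zero_everywhere(self):
        adj = np.zeros((5, 5))
        adj[0, 1:] = adj[1:, 0] = 0.8
        for i in range(5):
            assert local_clustering(adj, i) == 0.0

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(20):
            adj = random_sparse_sym(rng, 6, signed=True)
            coeffs = clustering_coefficients(adj)
            for i in range(6):
                assert coeffs[i] == pytest.approx(
                    brute_force_clustering(adj, i), abs=1e-12
                )

    def test_matches_networkx_onnela(self, rng):
        """Cross-check against networkx's weighted clustering (the geometric
        mean triangle-intensity definition with max-weight normalization)."""
        nx = pytest.importorskip("networkx")
        for seed in range(5):
            local_rng = np.random.default_rng(seed)
            adj = random_sparse_sym(local_rng, 10)
            g = nx.from_numpy_array(adj)
            expected = nx.clustering(g, weight="weight")
            coeffs = clustering_coefficients(adj)
            for i in range(10):
                assert coeffs[i] == pytest.approx(expected[i], abs=1e-10)

    def test_bounded_and_reduces_to_binary(self, rng):
        adj = random_sparse_sym(rng, 12)
        coeffs = clustering_coefficients(adj)
        assert np.all((coeffs >= 0) & (coeffs <= 1 + 1e-12))
        # all retained weights equal -> binary clustering coefficient
        binary = (adj > 0).astype(float) * 0.6
        nx = pytest.importorskip("networkx")
        expected = nx.clustering(nx.from_numpy_array(binary > 0))
        coeffs_bin = clustering_coefficients(binary)
        for i in range(12):
            assert coeffs_bin[i] == pytest.approx(expected[i], abs=1e-10)

    def test_asymmetric_input_rejected(self):
        adj = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            clustering_coefficients(adj)

    def test_literal_single_neighbour_variant(self, rng):
        adj = random_sparse_sym(rng, 6)
        coeffs = clustering_coefficients(adj, eq3_literal=True)
        w = adj / adj.max()
        for i in range(6):
            k = int((w[i] > 0).sum())
            expected = 2 * np.cbrt(w[i]).sum() / (k * (k - 1)) if k >= 2 else 0.0
            assert coeffs[i] == pytest.approx(expected, abs=1e-12)


class TestNodeFeatureSequence:
    def test_zero_off_diagonal_gives_zero_features(self):
        mats = np.tile(np.eye(5), (3, 1, 1))
        feats = node_feature_sequence(DynamicFC("s", "low", mats))
        np.testing.assert_array_equal(feats, 0.0)

    def test_identical_windows_identical_rows(self, rng):
        m = random_sparse_sym(rng, 7)
        np.fill_diagonal(m, 1.0)
        mats = np.tile(m, (4, 1, 1))
        feats = node_feature_sequence(DynamicFC("s", "low", mats))
        for k in range(1, 4):
            np.testing.assert_array_equal(feats[k], feats[0])

    def test_rows_equal_per_window_computation(self, rng):
        fc = random_symmetric_fc(rng, R=6, K=3)
        feats = node_feature_sequence(fc)
        for k in range(3):
            np.testing.assert_allclose(
                feats[k], clustering_coefficients(fc.matrices[k]), atol=1e-12
            )


class TestNormalizeAdjacency:
    def test_zero_input_gives_identity(self):
        np.testing.assert_allclose(normalize_adjacency(np.zeros((4, 4))), np.eye(4))

    def test_symmetric_output_and_spectral_radius(self, rng):
        for _ in range(10):
            adj = random_sparse_sym(rng, 9, signed=True)
            out = normalize_adjacency(adj)
            np.testing.assert_allclose(out, out.T, atol=1e-12)
            assert np.abs(np.linalg.eigvalsh(out)).max() <= 1 + 1e-9

    def test_matches_explicit_formula(self, rng):
        adj = random_sparse_sym(rng, 6, signed=True)
        a = np.abs(adj)
        np.fill_diagonal(a, 0.0)
        a_tilde = a + np.eye(6)
        d = a_tilde.sum(axis=1)
        expected = np.diag(d**-0.5) @ a_tilde @ np.diag(d**-0.5)
        np.testing.assert_allclose(normalize_adjacency(adj), expected, atol=1e-12)

    def test_sparsity_pattern_preserved(self, rng):
        adj = random_sparse_sym(rng, 8)
        out = normalize_adjacency(adj)
        expected_pattern = (adj != 0) | np.eye(8, dtype=bool)
        np.testing.assert_array_equal(out != 0, expected_pattern)

    def test_clip_zero_policy_drops_negative_edges(self):
        adj = np.array([[0.0, -0.5, 0.4], [-0.5, 0.0, 0.0], [0.4, 0.0, 0.0]])
        out = normalize_adjacency(adj, negative_policy="clip_zero")
        assert out[0, 1] == 0.0
        assert out[0, 2] > 0.0


def test_permutation_equivariance(rng):
    """Relabeling nodes permutes features and conjugates the adjacency."""
    fc = random_symmetric_fc(rng, R=7, K=2)
    perm = rng.permutation(7)
    fc_perm = DynamicFC("s", "low", fc.matrices[:, perm][:, :, perm])
    seq = build_graph_sequence(fc)
    seq_perm = build_graph_sequence(fc_perm)
    np.testing.assert_allclose(
        seq_perm.node_features, seq.node_features[:, perm], atol=1e-12
    )
    np.testing.assert_allclose(
        seq_perm.norm_adj, seq.norm_adj[:, perm][:, :, perm], atol=1e-12
    )
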