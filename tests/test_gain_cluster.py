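"""Input-gain amplification, PCA embedding, SNN-Leiden clustering and
recovery metrics."""

import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from raregain.gain import (
    GainSpec,
    apply_input_gain,
    build_graph_and_cluster,
    identify_marker_cluster,
    marker_threshold_select,
    pca_embed,
    recovery_metrics,
    umap_embed,
)
from raregain.io import NormalizedMatrix
from raregain.qc import scale_features, select_hvg


def _norm(dense, gene_ids=None):
    dense = np.asarray(dense, dtype=float)
    gene_ids = gene_ids or [f"G{i:04d}" for i in range(dense.shape[1])]
    return NormalizedMatrix(
        values=sp.csr_matrix(dense),
        cell_ids=[f"C{i}" for i in range(dense.shape[0])],
        gene_ids=gene_ids,
    )


class TestInputGain:
    def test_marker_columns_scaled_five_fold(self):
        norm = _norm([[0.0, 1.0], [1.2, 2.0]], gene_ids=["MK", "OTHER"])
        out = apply_input_gain(norm, GainSpec(marker_genes=["MK"], gain=5.0))
        np.testing.assert_array_equal(
            out.values.toarray(), [[0.0, 1.0], [6.0, 2.0]]
        )
        assert out.column_gain.tolist() == [5.0, 1.0]
        assert norm.values[1, 0] == 1.2  # input untouched

    def test_gain_one_is_exact_identity(self):
        norm = _norm(np.random.default_rng(0).poisson(2, (10, 5)))
        out = apply_input_gain(norm, GainSpec(marker_genes=["G0001"], gain=1.0))
        assert (out.values != norm.values).nnz == 0
        np.testing.assert_array_equal(out.forced_hvg, norm.forced_hvg)
        np.testing.assert_array_equal(out.column_gain, norm.column_gain)

    def test_gain_inverts_exactly(self):
        norm = _norm(np.random.default_rng(1).random((20, 4)))
        g = 5.0
        out = apply_input_gain(norm, GainSpec(marker_genes=["G0002"], gain=g))
        restored = out.values.toarray()
        restored[:, 2] /= g
        np.testing.assert_allclose(restored, norm.values.toarray(), atol=1e-12)

    def test_missing_marker_error_names_gene(self):
        norm = _norm(np.ones((3, 2)))
        with pytest.raises(KeyError, match="NOPE"):
            apply_input_gain(norm, GainSpec(marker_genes=["NOPE"], gain=5.0))

    def test_invalid_gain_rejected(self):
        with pytest.raises(ValueError):
            GainSpec(marker_genes=["A"], gain=0.5)
        with pytest.raises(ValueError):
            GainSpec(marker_genes=[], gain=5.0)


class TestPca:
    def test_rank_one_matrix_single_component(self):
        rng = np.random.default_rng(2)
        mat = np.outer(rng.normal(size=80), rng.normal(size=12))
        emb = pca_embed(mat, n_pcs=3, seed=0)
        var = emb.var(axis=0)
        assert var[0] / var.sum() > 0.99999

    def test_scores_are_centered(self):
        mat = np.random.default_rng(3).normal(size=(60, 10))
        emb = pca_embed(mat, n_pcs=4, seed=0)
        assert np.abs(emb.mean(axis=0)).max() < 1e-8

    def test_matches_dense_svd_oracle(self):
        rng = np.random.default_rng(4)
        mat = rng.normal(size=(100, 20))
        emb = pca_embed(mat, n_pcs=5, seed=0)
        centered = mat - mat.mean(axis=0)
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        oracle = u[:, :5] * s[:5]
        for k in range(5):  # apply the same sign convention
            j = int(np.argmax(np.abs(vt[k])))
            if vt[k, j] < 0:
                oracle[:, k] *= -1
        np.testing.assert_allclose(emb, oracle, atol=1e-6)

    def test_randomized_solver_is_seeded_and_sign_fixed(self):
        rng = np.random.default_rng(5)
        mat = rng.normal(size=(700, 40))  # large enough for randomized path
        a = pca_embed(mat, n_pcs=6, seed=9)
        b = pca_embed(mat, n_pcs=6, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            pca_embed(np.ones((5, 3)), n_pcs=4)


class TestClustering:
    def _blobs(self, sep=50.0, n=60, d=5, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(n, d))
        b = rng.normal(size=(n, d))
        b[:, 0] += sep
        return np.vstack([a, b]), np.r_[np.zeros(n), np.ones(n)]

    def test_two_separated_blobs_recovered_exactly(self):
        emb, truth = self._blobs()
        # resolution suited to a 120-node toy graph; 1.0 over-partitions
        labels = build_graph_and_cluster(
            emb, k_neighbors=10, resolution=0.3, seed=0
        )
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_same_seed_same_labels(self):
        emb, _ = self._blobs(sep=3.0, seed=1)
        a = build_graph_and_cluster(emb, seed=5)
        b = build_graph_and_cluster(emb, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_low_resolution_gives_single_cluster(self):
        rng = np.random.default_rng(6)
        emb = rng.normal(size=(80, 4))  # one blob: connected SNN graph
        labels = build_graph_and_cluster(emb, resolution=1e-3, seed=0)
        assert len(np.unique(labels)) == 1

    def test_k_lowered_with_warning_for_tiny_input(self):
        emb = np.random.default_rng(7).normal(size=(8, 3))
        with pytest.warns(UserWarning, match="lowering"):
            labels = build_graph_and_cluster(emb, k_neighbors=20, seed=0)
        assert len(labels) == 8

    def test_labels_are_a_partition_ordered_by_size(self):
        emb, _ = self._blobs(n=40, seed=2)
        emb = np.vstack([emb, emb[:10] + [0, 100, 0, 0, 0]])
        labels = build_graph_and_cluster(emb, k_neighbors=5, seed=0)
        sizes = np.bincount(labels)
        assert sizes.sum() == len(labels)
        assert all(sizes[i] >= sizes[i + 1] for i in range(len(sizes) - 1))


class TestMarkerCluster:
    def test_pure_double_positive_cluster_wins(self):
        dense = np.zeros((6, 2))
        dense[:3] = 1.0  # cells 0-2 double positive
        norm = _norm(dense, gene_ids=["M1", "M2"])
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert identify_marker_cluster(labels, norm, ["M1", "M2"]) == 0

    def test_no_qualifying_cluster_returns_none(self):
        norm = _norm(np.zeros((4, 2)), gene_ids=["M1", "M2"])
        labels = np.array([0, 0, 1, 1])
        assert identify_marker_cluster(labels, norm, ["M1", "M2"]) is None

    def test_tie_breaks_prefer_larger_then_lower_id(self):
        # clusters 1 (3 cells) and 2 (2 cells) both 100% double positive
        dense = np.ones((7, 2))
        dense[:2] = 0.0  # cluster 0 is negative
        norm = _norm(dense, gene_ids=["M1", "M2"])
        labels = np.array([0, 0, 1, 1, 1, 2, 2])
        assert identify_marker_cluster(labels, norm, ["M1", "M2"]) == 1
        # equal sizes: lower id wins
        labels = np.array([0, 0, 0, 1, 1, 2, 2])
        dense2 = np.ones((7, 2))
        dense2[:3] = 0.0
        norm2 = _norm(dense2, gene_ids=["M1", "M2"])
        assert identify_marker_cluster(labels, norm2, ["M1", "M2"]) == 1


class TestThresholdSelection:
    def test_all_marker_positive_rule(self):
        dense = np.zeros((10, 3))
        dense[[1, 4, 7], 0] = 1.0
        dense[[1, 4, 7], 1] = 2.0
        dense[2, 0] = 5.0  # single positive: excluded
        norm = _norm(dense, gene_ids=["M1", "M2", "X"])
        cells = marker_threshold_select(norm, ["M1", "M2"])
        assert cells == {"C1", "C4", "C7"}


class TestRecoveryMetrics:
    def test_cluster_equals_threshold_set(self):
        m = recovery_metrics({"a", "b"}, {"a", "b"}, total_cells=10)
        assert m.recovery_fraction == 1.0 and m.precision == 1.0
        assert m.population_fraction == 0.2

    def test_large_cohort_recovery_fraction_rounding(self):
        cluster = {f"c{i}" for i in range(285)}
        threshold = {f"c{i}" for i in range(437)}
        m = recovery_metrics(cluster, threshold, total_cells=208_506)
        assert round(m.recovery_fraction, 3) == 0.652
        assert m.precision == 1.0

    def test_disjoint_sets_and_empty_threshold(self):
        assert recovery_metrics({"a"}, {"b"}, 5).recovery_fraction == 0.0
        assert recovery_metrics({"a"}, set(), 5).recovery_fraction is None
        assert recovery_metrics(set(), {"b"}, 5).precision is None


def test_umap_is_seed_deterministic_with_expected_shape():
    emb = np.random.default_rng(8).normal(size=(60, 6))
    a = umap_embed(emb, seed=3)
    b = umap_embed(emb, seed=3)
    assert a.shape == (60, 2)
    np.testing.assert_allclose(a, b, atol=1e-6)


def test_gained_pipeline_amplifies_scaled_marker(small_dataset):
    """Scaled marker columns under gain g are exactly g times the ungained
    scaled values (the standardization exemption)."""
    from raregain.qc import filter_cells, lognormalize

    kept = filter_cells(small_dataset.counts, small_dataset.gene_table)
    norm = lognormalize(kept)
    markers = list(small_dataset.config.marker_genes)

    plain = apply_input_gain(norm, GainSpec(marker_genes=markers, gain=1.0))
    select_hvg(plain, n_top=100)
    plain.hvg_mask[plain.gene_index(markers)] = True
    scaled_plain = scale_features(plain, clip=1e9)

    gained = apply_input_gain(norm, GainSpec(marker_genes=markers, gain=5.0))
    gained.hvg_mask = plain.hvg_mask.copy()
    scaled_gained = scale_features(gained, clip=1e9)

    hvg_idx = np.flatnonzero(plain.hvg_mask)
    marker_pos = [list(hvg_idx).index(j) for j in plain.gene_index(markers)]
    for c in range(scaled_plain.shape[1]):
        factor = 5.0 if c in marker_pos else 1.0
        np.testing.assert_allclose(
            scaled_gained[:, c], factor * scaled_plain[:, c], atol=1e-9
        )
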