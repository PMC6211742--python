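"""PCA/elbow, SNN modularity clustering, tSNE and marker annotation."""

import igraph
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from serocell.cluster import (
    ClusterResult,
    annotate_clusters,
    cluster_graph,
    pca_embed,
    select_elbow,
    snn_cluster,
    tsne_embed,
)
from serocell.core import GeneSet, SerocellError
from serocell.preprocess import NormalizedMatrix

from conftest import preprocess_to_pcs


def as_norm(values):
    g, c = values.shape
    return NormalizedMatrix(
        [f"g{i}" for i in range(g)], [f"c{j}" for j in range(c)], values
    )


def two_blobs(seed, n=50, sep=10.0, dim=5):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n, dim))
    b = rng.normal(sep, 1.0, size=(n, dim))
    return np.vstack([a, b]), np.r_[np.zeros(n), np.ones(n)]


class TestPCA:
    def test_rank_one_matrix_concentrates_variance(self):
        u = np.arange(1, 11, dtype=float)
        v = np.linspace(-1, 1, 30)
        res = pca_embed(as_norm(np.outer(u, v)), 5)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-8)
        assert np.all(res.variance_fractions[1:] < 1e-8)

    def test_full_scores_preserve_pairwise_distances(self):
        """With all components kept, PCA is an isometry of the centered cells."""
        rng = np.random.default_rng(0)
        values = rng.normal(size=(20, 15))  # 15 cells, 20 genes
        res = pca_embed(as_norm(values), 15)
        x = values.T - values.T.mean(axis=0)
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(res.scores), pdist(x), atol=1e-6)

    def test_component_sign_flip_leaves_distances_unchanged(self):
        rng = np.random.default_rng(1)
        res = pca_embed(as_norm(rng.normal(size=(30, 25))), 5)
        from scipy.spatial.distance import pdist

        flipped = res.scores.copy()
        flipped[:, 2] *= -1
        assert np.allclose(pdist(flipped), pdist(res.scores))

    def test_too_many_components_raises(self):
        with pytest.raises(SerocellError):
            pca_embed(as_norm(np.ones((5, 4))), 10)


class TestElbow:
    @staticmethod
    def brute_force_elbow(v):
        v = np.asarray(v, dtype=float)
        n = v.size
        p0, p1 = np.array([1.0, v[0]]), np.array([float(n), v[-1]])
        u = p1 - p0
        norm = np.linalg.norm(u)
        best_k, best_d = 1, -1.0
        for k in range(1, n + 1):  # ties -> smaller k
            d = abs(u[0] * (v[k - 1] - p0[1]) - u[1] * (k - p0[0])) / norm
            if d > best_d + 1e-15:
                best_k, best_d = k, d
        return best_k

    def test_matches_brute_force_over_random_screes(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            v = np.sort(rng.random(rng.integers(3, 30)))[::-1]
            v = v / (v.sum() * 1.5)
            assert select_elbow(v) == self.brute_force_elbow(v)

    def test_single_dominant_component(self):
        v = np.r_[0.5, np.linspace(0.049, 0.047, 20)]
        assert select_elbow(v) <= 2

    def test_linear_decay_warns(self, caplog):
        with caplog.at_level("WARNING"):
            select_elbow(np.linspace(0.3, 0.1, 10))
        assert "straight line" in caplog.text

    def test_too_few_fractions_raise(self):
        with pytest.raises(SerocellError):
            select_elbow(np.array([0.6, 0.4]))


class TestSNNCluster:
    def test_two_separated_blobs_recovered_every_seed(self):
        for seed in range(20):
            emb, labels = two_blobs(seed)
            res = snn_cluster(emb, k_neighbors=15, seed=seed)
            assert res.n_clusters == 2
            assert adjusted_rand_score(labels, res.labels) == 1.0

    def test_modularity_beats_trivial_partition(self):
        emb, _ = two_blobs(0)
        res = snn_cluster(emb, k_neighbors=15, seed=0)
        assert res.modularity > 0.0  # one-cluster partition has modularity 0

    def test_cell_order_permutation_is_consistent(self):
        emb, _ = two_blobs(3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(emb.shape[0])
        a = snn_cluster(emb, k_neighbors=15, seed=1)
        b = snn_cluster(emb[perm], k_neighbors=15, seed=1)
        assert adjusted_rand_score(a.labels[perm], b.labels) == 1.0

    @pytest.mark.parametrize(
        "edges,n",
        [
            # two triangles joined by a bridge
            ([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)], 6),
            # two squares joined by a bridge
            ([(0, 1), (1, 2), (2, 3), (3, 0), (4, 5), (5, 6), (6, 7), (7, 4), (0, 4)], 8),
            # 5-path
            ([(0, 1), (1, 2), (2, 3), (3, 4)], 5),
        ],
    )
    def test_toy_graph_modularity_equals_exhaustive_maximum(self, edges, n):
        g = igraph.Graph(n=n, edges=edges)
        g.es["weight"] = [1.0] * len(edges)
        _, achieved = cluster_graph(g, seed=0)
        best = max(
            g.modularity(p, weights=g.es["weight"]) for p in _all_partitions(n)
        )
        assert achieved == pytest.approx(best, abs=1e-12)


def _all_partitions(n):
    """Enumerate all set partitions of range(n) as membership vectors."""
    if n == 0:
        yield []
        return
    for rest in _all_partitions(n - 1):
        k = max(rest, default=-1) + 1
        for label in range(k + 1):
            yield rest + [label]


class TestTSNE:
    def test_deterministic_given_seed(self):
        emb, _ = two_blobs(4, n=30)
        assert np.array_equal(tsne_embed(emb, seed=0), tsne_embed(emb, seed=0))

    def test_separated_blobs_stay_separated(self):
        emb, labels = two_blobs(5, n=40)
        coords = tsne_embed(emb, seed=0)
        a, b = coords[labels == 0], coords[labels == 1]
        gap = np.linalg.norm(a.mean(axis=0) - b.mean(axis=0))
        spread = max(
            np.linalg.norm(a - a.mean(axis=0), axis=1).max(),
            np.linalg.norm(b - b.mean(axis=0), axis=1).max(),
        )
        assert gap > spread

    def test_too_few_cells_raise(self):
        with pytest.raises(SerocellError):
            tsne_embed(np.zeros((4, 3)), seed=0)


class TestAnnotate:
    def test_pure_marker_cluster_labeled(self):
        values = np.zeros((4, 10))
        values[0:2, :] = 1.0  # EPCAM, KRT8 detected everywhere
        norm = NormalizedMatrix(
            ["EPCAM", "KRT8", "PTPRC", "CD3E"], [f"c{j}" for j in range(10)], values
        )
        clusters = ClusterResult(np.zeros(10, dtype=int), 1, 0.0)
        panels = [
            GeneSet("epithelial", ["EPCAM", "KRT8"]),
            GeneSet("lymphocyte", ["PTPRC", "CD3E"]),
        ]
        out = annotate_clusters(norm, clusters, panels)
        assert out.annotations[0] == "epithelial"

    def test_all_zero_cluster_unassigned(self):
        norm = NormalizedMatrix(["EPCAM"], [f"c{j}" for j in range(6)], np.zeros((1, 6)))
        clusters = ClusterResult(np.zeros(6, dtype=int), 1, 0.0)
        out = annotate_clusters(norm, clusters, [GeneSet("epithelial", ["EPCAM"])])
        assert out.annotations[0] == "unassigned"

    def test_tie_yields_unassigned(self, caplog):
        values = np.ones((2, 8))
        norm = NormalizedMatrix(["A", "B"], [f"c{j}" for j in range(8)], values)
        clusters = ClusterResult(np.zeros(8, dtype=int), 1, 0.0)
        with caplog.at_level("WARNING"):
            out = annotate_clusters(
                norm, clusters, [GeneSet("t1", ["A"]), GeneSet("t2", ["B"])]
            )
        assert out.annotations[0] == "unassigned"
        assert "tied" in caplog.text

    def test_site_majority_suffix(self):
        values = np.ones((1, 10))
        norm = NormalizedMatrix(["CD14"], [f"c{j}" for j in range(10)], values)
        clusters = ClusterResult(np.zeros(10, dtype=int), 1, 0.0)
        sites = ["metastatic"] * 8 + ["primary"] * 2
        out = annotate_clusters(
            norm, clusters, [GeneSet("myeloid", ["CD14"])], sites=sites
        )
        assert out.annotations[0] == "myeloid/metastatic"


class TestEndToEnd:
    def test_six_type_cohort_annotation_agreement(self, balanced_cohort):
        """Clusters recover truth types and marker panels name them correctly."""
        counts, meta, truth = balanced_cohort
        filtered, norm, pcs = preprocess_to_pcs(counts)
        res = snn_cluster(pcs, seed=0)
        kept = {bc: i for i, bc in enumerate(filtered.barcodes)}
        tt = [t for m, t in zip(meta, truth.cell_types) if m.barcode in kept]
        assert adjusted_rand_score(tt, res.labels) >= 0.9

        panels = [
            GeneSet(name, [counts.genes[i] for i in np.flatnonzero(truth.effects[:, k])])
            for k, name in enumerate(truth.type_names)
        ]
        out = annotate_clusters(norm, res, panels)
        tt = np.array(tt)
        agree = 0
        for k in range(res.n_clusters):
            members = res.labels == k
            majority = max(set(tt[members]), key=list(tt[members]).count)
            agree += out.annotations[k] == majority
        assert agree / res.n_clusters >= 0.95
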