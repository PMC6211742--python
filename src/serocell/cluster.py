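"""PCA with elbow selection, SNN-graph modularity clustering, tSNE embedding
and marker-panel cluster annotation.

Clustering follows the standard droplet workflow: Euclidean k-nearest
neighbors in PC space define a shared-nearest-neighbor (SNN) graph with
Jaccard edge weights, weak edges are pruned, and the partition is found by
seeded Louvain-style modularity optimization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
from scipy.sparse import csr_matrix
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from serocell.core import GeneSet, SerocellError
from serocell.preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    """Cells x k principal-component scores with explained-variance fractions."""

    scores: np.ndarray
    variance_fractions: np.ndarray

    def __post_init__(self) -> None:
        vf = np.asarray(self.variance_fractions, dtype=float)
        if np.any(np.diff(vf) > 1e-12):
            raise SerocellError("variance fractions must be non-increasing")
        if vf.min() < -1e-12 or vf.sum() > 1 + 1e-9:
            raise SerocellError("variance fractions must lie in [0, 1] and sum <= 1")
        self.variance_fractions = vf


@dataclass
class ClusterResult:
    """A partition of cells into clusters, optionally annotated."""

    labels: np.ndarray
    n_clusters: int
    modularity: float
    annotations: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and set(self.labels) != set(range(self.n_clusters)):
            raise SerocellError("cluster ids must be 0..K-1 with every id used")


# A marker panel is simply a named gene set whose name is the cell type.
MarkerPanel = GeneSet


def pca_embed(scaled: NormalizedMatrix, n_components: int) -> PCAResult:
    """Project cells onto the top principal components of the scaled matrix.

    The input is genes x cells; cells are observations.  Uses a full SVD
    for determinism.
    """
    x = scaled.values.T  # cells x genes
    if n_components > min(x.shape):
        raise SerocellError(
            f"n_components={n_components} exceeds min(genes, cells)={min(x.shape)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    return PCAResult(scores, pca.explained_variance_ratio_)


def select_elbow(variance_fractions: np.ndarray) -> int:
    """Pick the number of PCs at the elbow of the scree curve.

    The elbow is the 1-based index with maximum perpendicular distance to
    the chord from ``(1, v_1)`` to ``(n, v_n)``; ties break toward smaller
    k.  A degenerate (straight-line) scree emits a warning and yields an
    endpoint-adjacent k.
    """
    v = np.asarray(variance_fractions, dtype=float)
    if v.size < 3:
        raise SerocellError("need at least 3 variance fractions")
    x = np.arange(1, v.size + 1, dtype=float)
    dx, dy = x[-1] - x[0], v[-1] - v[0]
    dist = np.abs(dy * (x - x[0]) - dx * (v - v[0])) / np.hypot(dx, dy)
    if dist.max() < 1e-12:
        logger.warning("scree curve is a straight line; elbow ill-defined")
    return int(np.argmax(dist)) + 1


def snn_graph(
    embeddings: np.ndarray, k_neighbors: int = 20, prune: float = 1 / 15
) -> igraph.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Each cell's neighborhood is itself plus its ``k_neighbors`` Euclidean
    nearest neighbors in PC space; the edge weight between two cells is the
    Jaccard overlap of their neighborhoods, and edges below ``prune`` are
    dropped.
    """
    n = embeddings.shape[0]
    if n < k_neighbors + 1:
        raise SerocellError(f"need more than k_neighbors={k_neighbors} cells, got {n}")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(embeddings)
    _, idx = nn.kneighbors(embeddings)  # includes self at distance 0
    size = k_neighbors + 1
    rows = np.repeat(np.arange(n), size)
    adj = csr_matrix((np.ones(n * size), (rows, idx.ravel())), shape=(n, n))
    shared = adj @ adj.T  # |N(i) & N(j)|
    shared = shared.tocoo()
    mask = shared.row < shared.col
    inter = shared.data[mask]
    jaccard = inter / (2 * size - inter)
    keep = jaccard >= prune
    edges = list(zip(shared.row[mask][keep].tolist(), shared.col[mask][keep].tolist()))
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = jaccard[keep].tolist()
    return g


def cluster_graph(
    graph: igraph.Graph, resolution: float = 1.0, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Seeded modularity optimization on a weighted graph.

    Returns 0-based membership labels and the modularity of the partition
    (standard Newman-Girvan modularity with edge weights).
    """
    weights = graph.es["weight"] if "weight" in graph.es.attributes() else None
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    modularity = graph.modularity(part.membership, weights=weights)
    return labels, modularity


def snn_cluster(
    embeddings: np.ndarray,
    k_neighbors: int = 20,
    prune: float = 1 / 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> ClusterResult:
    """Cluster cells by SNN-graph modularity optimization in PC space."""
    g = snn_graph(embeddings, k_neighbors=k_neighbors, prune=prune)
    labels, modularity = cluster_graph(g, resolution=resolution, seed=seed)
    n_singletons = int(np.sum(np.bincount(labels) == 1))
    if n_singletons:
        logger.info("%d cells are singleton clusters", n_singletons)
    return ClusterResult(labels, int(labels.max()) + 1, modularity)


def tsne_embed(
    embeddings: np.ndarray, seed: int = 0, perplexity: float | None = None
) -> np.ndarray:
    """2-D tSNE of the PC scores, for visualization only."""
    n = embeddings.shape[0]
    if n < 5:
        raise SerocellError(f"need at least 5 cells for tSNE, got {n}")
    if perplexity is None:
        perplexity = min(30.0, (n - 1) / 3)
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        learning_rate="auto",
    )
    return tsne.fit_transform(embeddings)


def annotate_clusters(
    norm: NormalizedMatrix,
    clusters: ClusterResult,
    panels: list[MarkerPanel],
    min_frac: float = 0.25,
    sites: list[str] | None = None,
    site_majority: float = 0.6,
) -> ClusterResult:
    """Label clusters by their best-detected marker panel.

    A panel's score in a cluster is the mean, over the panel's genes
    present in the matrix, of the fraction of the cluster's cells
    detecting the gene (expression > 0).  The cluster is labeled with the
    argmax panel if its score reaches ``min_frac``; ties or weak maxima
    yield ``"unassigned"``.  If per-cell ``sites`` are supplied and one
    site exceeds ``site_majority`` of a cluster, the label is suffixed
    with it (e.g. ``"myeloid/metastatic"``).
    """
    gene_pos = {g: i for i, g in enumerate(norm.genes)}
    panel_idx = []
    for p in panels:
        idx = [gene_pos[g] for g in p.genes if g in gene_pos]
        missing = len(p.genes) - len(idx)
        if missing:
            logger.warning("panel %s: %d genes absent from the matrix", p.name, missing)
        panel_idx.append(np.asarray(idx, dtype=int))
    if all(idx.size == 0 for idx in panel_idx):
        raise SerocellError("no marker panel overlaps the gene universe")

    detected = norm.values > 0
    annotations: dict[int, str] = {}
    for k in range(clusters.n_clusters):
        members = clusters.labels == k
        scores = np.array(
            [detected[np.ix_(idx, members)].mean(axis=1).mean() if idx.size else 0.0
             for idx in panel_idx]
        )
        best = scores.max()
        winners = np.flatnonzero(scores == best)
        if best < min_frac:
            label = "unassigned"
        elif winners.size > 1:
            logger.warning(
                "cluster %d: tied panels %s; unassigned",
                k,
                [panels[w].name for w in winners],
            )
            label = "unassigned"
        else:
            label = panels[int(winners[0])].name
        if label != "unassigned" and sites is not None:
            member_sites = [sites[i] for i in np.flatnonzero(members)]
            top = max(set(member_sites), key=member_sites.count)
            if member_sites.count(top) / len(member_sites) > site_majority:
                label = f"{label}/{top}"
        annotations[k] = label
    return ClusterResult(
        clusters.labels, clusters.n_clusters, clusters.modularity, annotations
    )
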