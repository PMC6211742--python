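"""Per-sample cell-type composition, hierarchical sample grouping and Fisher
exact enrichment of a cell type in a sample.

These are the population-level analyses of a tumor cohort: how the mix of
epithelial, immune and stromal cells differs between samples (e.g. the
shift from epithelial-dominated primary tumors to lymphocyte-dominated
metastases), which samples group together by composition, and whether a
particular cell type (such as B cells) is significantly enriched in one
sample relative to all others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import fisher_exact

from serocell.core import CellMeta, SerocellError

logger = logging.getLogger(__name__)


@dataclass
class CompositionTable:
    """Samples x cell-type counts with row-normalized proportions."""

    counts: pd.DataFrame
    proportions: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise SerocellError("composition counts must be non-negative")
        rows = self.proportions.sum(axis=1).to_numpy()
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise SerocellError("proportion rows must sum to 1")


def composition_table(meta: list[CellMeta]) -> CompositionTable:
    """Cross-tabulate cells by sample and assigned cell type."""
    missing = [m.barcode for m in meta if m.cell_type is None]
    if missing:
        raise SerocellError(
            f"{len(missing)} cells lack a cell_type label (e.g. {missing[0]})"
        )
    df = pd.DataFrame(
        {"sample": [m.sample_id for m in meta], "cell_type": [m.cell_type for m in meta]}
    )
    counts = pd.crosstab(df["sample"], df["cell_type"])
    props = counts.div(counts.sum(axis=1), axis=0)
    return CompositionTable(counts, props)


def cluster_samples(
    table: CompositionTable,
    metric: str = "euclidean",
    linkage: str = "ward",
    n_groups: int | None = None,
) -> tuple[np.ndarray, str, np.ndarray | None]:
    """Agglomerative clustering of samples on their composition profiles.

    Returns ``(linkage_matrix, newick, flat_labels)``; ``flat_labels`` is
    the ``n_groups``-cluster cut (1-based scipy convention) or None.
    """
    if table.proportions.shape[0] < 2:
        raise SerocellError("need at least 2 samples to cluster")
    z = hierarchy.linkage(table.proportions.to_numpy(), method=linkage, metric=metric)
    newick = _linkage_to_newick(z, list(table.proportions.index))
    flat = None
    if n_groups is not None:
        flat = hierarchy.fcluster(z, t=n_groups, criterion="maxclust")
    return z, newick, flat


def _linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(z)

    def recurse(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return recurse(tree, tree.dist) + ";"


def fisher_enrichment(
    table: CompositionTable, cell_type: str, sample: str
) -> tuple[float, float]:
    """Two-sided Fisher exact test of a cell type's enrichment in a sample.

    The 2x2 table is [[type in sample, other in sample], [type elsewhere,
    other elsewhere]].  The p-value sums hypergeometric probabilities not
    exceeding the observed table's (the minimum-likelihood convention).
    The reported odds ratio is the sample odds ratio ``ad/bc``; when a
    table cell is zero a 0.5 continuity correction is applied for display
    and flagged with a warning.
    """
    if sample not in table.counts.index:
        raise SerocellError(f"unknown sample {sample!r}")
    if cell_type not in table.counts.columns:
        raise SerocellError(f"unknown cell type {cell_type!r}")
    a = int(table.counts.loc[sample, cell_type])
    b = int(table.counts.loc[sample].sum() - a)
    c = int(table.counts[cell_type].sum() - a)
    d = int(table.counts.to_numpy().sum() - a - b - c)
    m = np.array([[a, b], [c, d]])
    if m.sum(axis=0).min() == 0 or m.sum(axis=1).min() == 0:
        raise SerocellError("degenerate 2x2 table: an entire margin is zero")
    _, p = fisher_exact(m, alternative="two-sided")
    if min(a, b, c, d) == 0:
        logger.warning("zero cell in 2x2 table; odds ratio uses 0.5 continuity")
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = a * d / (b * c)
    return float(odds), float(p)
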