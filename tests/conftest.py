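import numpy as np
import pytest

from serocell.core import CountMatrix
from serocell.preprocess import (
    NormalizedMatrix,
    filter_matrix,
    log_normalize,
    regress_covariates,
    scale_and_clip,
    select_variable_genes,
)
from serocell.synthetic import (
    CohortConfig,
    SampleSpec,
    default_cell_types,
    generate_cohort,
)

SIX_TYPES = ("epithelial", "tcell", "bcell", "myeloid", "fibroblast", "stromal")


def balanced_cohort_config(seed: int, n_cells: int = 600, n_genes: int = 1500) -> CohortConfig:
    """Six cell types in equal proportions within a single sample."""
    cell_types = default_cell_types(n_genes, names=SIX_TYPES)
    samples = [
        SampleSpec("S1", "P1", "primary", "HGSOC", n_cells, np.full(6, 1 / 6))
    ]
    return CohortConfig(n_genes=n_genes, cell_types=cell_types, samples=samples, seed=seed)


def preprocess_to_pcs(counts, n_components: int = 30):
    """Run the standard QC -> normalize -> scale -> HVG -> PCA chain."""
    from serocell.cluster import pca_embed, select_elbow

    filtered, _ = filter_matrix(counts)
    norm = log_normalize(filtered)
    zeros = np.zeros(filtered.n_cells)
    regressed = regress_covariates(norm, filtered.total_umis(), zeros, zeros)
    scaled = scale_and_clip(regressed)
    hvg = select_variable_genes(norm)
    gene_pos = {g: i for i, g in enumerate(scaled.genes)}
    idx = [gene_pos[g] for g in hvg]
    sub = NormalizedMatrix(
        [scaled.genes[i] for i in idx], list(scaled.barcodes), scaled.values[idx]
    )
    pca = pca_embed(sub, min(n_components, len(idx), filtered.n_cells))
    k = max(select_elbow(pca.variance_fractions), 2)
    return filtered, norm, pca.scores[:, :k]


@pytest.fixture(scope="session")
def balanced_cohort():
    """One seeded six-type cohort shared by clustering/annotation tests."""
    counts, meta, truth = generate_cohort(balanced_cohort_config(seed=7))
    return counts, meta, truth


@pytest.fixture
def tiny_counts():
    """3 genes x 4 cells with hand-checkable values."""
    mat = np.array(
        [
            [5, 0, 2, 0],
            [0, 3, 0, 0],
            [1, 1, 4, 2],
        ]
    )
    return CountMatrix(["GA", "GB", "GC"], ["c1", "c2", "c3", "c4"], mat)
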