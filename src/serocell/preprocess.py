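"""QC filtering, log-normalization, cell-cycle scoring, covariate regression
and variable-gene selection.

The defaults follow the common droplet convention: genes kept if detected
in >= 3 cells, cells kept if >= 200 genes detected (applied once, genes
first), counts scaled to 10^4 per cell and natural-log transformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from serocell.core import AllFilteredError, CountMatrix, GeneSet, SerocellError

logger = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """Dense genes x cells real-valued expression with provenance."""

    genes: list[str]
    barcodes: list[str]
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.barcodes)):
            raise SerocellError("normalized matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise SerocellError("normalized matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)


@dataclass
class CellCycleScores:
    """Per-cell S-phase and G2/M-phase scores (dimensionless)."""

    s_score: np.ndarray
    g2m_score: np.ndarray

    def __post_init__(self) -> None:
        self.s_score = np.asarray(self.s_score, dtype=float)
        self.g2m_score = np.asarray(self.g2m_score, dtype=float)
        if self.s_score.shape != self.g2m_score.shape:
            raise SerocellError("cell-cycle score vectors differ in length")
        if not (np.all(np.isfinite(self.s_score)) and np.all(np.isfinite(self.g2m_score))):
            raise SerocellError("cell-cycle scores contain non-finite values")


def filter_matrix(
    counts: CountMatrix, min_cells: int = 3, min_genes: int = 200
) -> tuple[CountMatrix, dict]:
    """Remove rarely detected genes, then low-complexity cells.

    Genes must be detected (count > 0) in at least ``min_cells`` cells;
    cells must then have at least ``min_genes`` detected genes among the
    retained genes.  Single pass, genes first.  Returns the filtered
    matrix and a report with both removal counts.
    """
    gene_keep = np.flatnonzero(counts.cells_per_gene() >= min_cells)
    if gene_keep.size == 0:
        raise AllFilteredError("gene filter removed every gene")
    trimmed = counts.subset(gene_idx=gene_keep)
    cell_keep = np.flatnonzero(trimmed.genes_detected() >= min_genes)
    if cell_keep.size == 0:
        raise AllFilteredError("cell filter removed every cell")
    out = trimmed.subset(cell_idx=cell_keep)
    report = {
        "genes_removed": counts.n_genes - gene_keep.size,
        "cells_removed": counts.n_cells - cell_keep.size,
        "min_cells": min_cells,
        "min_genes": min_genes,
    }
    logger.info(
        "QC filter: removed %(genes_removed)d genes and %(cells_removed)d cells", report
    )
    return out, report


def log_normalize(counts: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """x_gi = ln(1 + c_gi * scale_factor / total_i), per-cell depth scaled."""
    totals = counts.total_umis().astype(float)
    if np.any(totals == 0):
        raise SerocellError("zero-total cell; run filter_matrix first")
    values = np.log1p(counts.counts.toarray() * (scale_factor / totals)[None, :])
    return NormalizedMatrix(
        list(counts.genes),
        list(counts.barcodes),
        values,
        {"scale_factor": scale_factor},
    )


def cell_cycle_score(
    norm: NormalizedMatrix,
    s_set: GeneSet,
    g2m_set: GeneSet,
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> CellCycleScores:
    """Score each cell for S and G2/M phase activity.

    For each phase the score is the mean expression of the phase genes
    minus the mean expression of a seeded control draw: ``n_ctrl`` genes
    sampled, for every phase gene, from the same average-expression bin
    (``n_bins`` equal-frequency bins over all genes).  Deterministic given
    ``seed``.
    """
    return CellCycleScores(
        _phase_score(norm, s_set, n_bins, n_ctrl, seed),
        _phase_score(norm, g2m_set, n_bins, n_ctrl, seed + 1),
    )


def _phase_score(
    norm: NormalizedMatrix, gene_set: GeneSet, n_bins: int, n_ctrl: int, seed: int
) -> np.ndarray:
    gene_pos = {g: i for i, g in enumerate(norm.genes)}
    idx = np.array([gene_pos[g] for g in gene_set.genes if g in gene_pos], dtype=int)
    if idx.size == 0:
        raise SerocellError(f"gene set {gene_set.name!r} shares no genes with the matrix")
    if idx.size < len(gene_set.genes):
        logger.warning(
            "gene set %s: %d of %d genes absent from the matrix",
            gene_set.name,
            len(gene_set.genes) - idx.size,
            len(gene_set.genes),
        )
    means = norm.values.mean(axis=1)
    # equal-frequency bins over the average expression of all genes
    order = np.argsort(means, kind="stable")
    bins = np.empty(norm.n_genes, dtype=int)
    bins[order] = np.minimum(
        np.arange(norm.n_genes) * n_bins // norm.n_genes, n_bins - 1
    )
    rng = np.random.default_rng(seed)
    ctrl: set[int] = set()
    for g in idx:
        pool = np.flatnonzero(bins == bins[g])
        take = min(n_ctrl, pool.size)
        ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
    ctrl_idx = np.fromiter(ctrl, dtype=int)
    return norm.values[idx].mean(axis=0) - norm.values[ctrl_idx].mean(axis=0)


def regress_covariates(
    norm: NormalizedMatrix,
    total_umis: np.ndarray,
    s_score: np.ndarray,
    g2m_score: np.ndarray,
) -> NormalizedMatrix:
    """Per-gene OLS of expression on [1, log10 total UMIs, S, G2M]; residuals out.

    Constant (rank-deficient) covariate columns are dropped with a warning.
    Residuals have zero mean per gene by construction.
    """
    n = norm.n_cells
    covs = {
        "log10_total_umis": np.log10(np.asarray(total_umis, dtype=float)),
        "s_score": np.asarray(s_score, dtype=float),
        "g2m_score": np.asarray(g2m_score, dtype=float),
    }
    cols = [np.ones(n)]
    used = ["intercept"]
    for name, v in covs.items():
        if v.shape != (n,):
            raise SerocellError(f"covariate {name} has wrong length")
        if not np.all(np.isfinite(v)):
            raise SerocellError(f"covariate {name} contains non-finite values")
        if np.ptp(v) == 0:
            logger.warning("covariate %s is constant; dropped from the design", name)
            continue
        cols.append(v)
        used.append(name)
    design = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(design, norm.values.T, rcond=None)
    residuals = norm.values - (design @ beta).T
    prov = dict(norm.provenance)
    prov["regressed"] = used[1:]
    return NormalizedMatrix(list(norm.genes), list(norm.barcodes), residuals, prov)


def scale_and_clip(norm: NormalizedMatrix, clip: float = 10.0) -> NormalizedMatrix:
    """Z-scale each gene and clip at +/- ``clip`` to bound outlier leverage."""
    mu = norm.values.mean(axis=1, keepdims=True)
    sd = norm.values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    values = np.clip((norm.values - mu) / sd, -clip, clip)
    prov = dict(norm.provenance)
    prov["scaled"] = {"clip": clip}
    return NormalizedMatrix(list(norm.genes), list(norm.barcodes), values, prov)


def select_variable_genes(
    norm: NormalizedMatrix,
    n_bins: int = 20,
    z_cutoff: float = 1.0,
    max_genes: int = 2000,
) -> list[str]:
    """Pick highly variable genes by binned dispersion z-scores.

    Dispersion is variance/mean of the back-transformed expression
    ``expm1(x)`` per gene.  Genes are binned by mean into ``n_bins``
    equal-frequency bins; within each bin the log dispersion is z-scored
    and genes with z >= ``z_cutoff`` are returned, capped at ``max_genes``
    by descending z.
    """
    if norm.n_genes < n_bins:
        raise SerocellError(f"need at least {n_bins} genes, got {norm.n_genes}")
    expr = np.expm1(norm.values)
    means = expr.mean(axis=1)
    variances = expr.var(axis=1)
    if np.all(variances == 0):
        logger.warning("constant matrix: no variable genes")
        return []
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(means > 0, variances / np.maximum(means, 1e-300), 0.0)
        log_disp = np.where(disp > 0, np.log(np.where(disp > 0, disp, 1.0)), -np.inf)
    order = np.argsort(means, kind="stable")
    bins = np.empty(norm.n_genes, dtype=int)
    bins[order] = np.minimum(np.arange(norm.n_genes) * n_bins // norm.n_genes, n_bins - 1)
    z = np.full(norm.n_genes, -np.inf)
    for b in range(n_bins):
        members = np.flatnonzero((bins == b) & np.isfinite(log_disp))
        if members.size == 0:
            continue
        vals = log_disp[members]
        sd = vals.std()
        z[members] = (vals - vals.mean()) / sd if sd > 0 else 0.0
    selected = np.flatnonzero(z >= z_cutoff)
    selected = selected[np.argsort(-z[selected], kind="stable")][:max_genes]
    logger.info("selected %d variable genes (z >= %.2f)", selected.size, z_cutoff)
    return [norm.genes[i] for i in selected]
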