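"""Zero-inflated negative-binomial cohort simulator with known ground truth.

The generative model mirrors the structure of a droplet scRNA-seq tumor
cohort: fourteen-or-fewer samples from several patients, each a mixture of
epithelial, lymphoid, myeloid, fibroblast, stromal and endothelial cells
whose composition depends on the anatomical site (primary tumors dominated
by epithelial cells, omental metastases by lymphocytes).

For cell i of type t and gene g the UMI count is drawn from a zero-inflated
negative binomial with

    mu_gi  = s_i * lambda_g * 2**f_gt          (mean)
    theta_g                                     (dispersion)
    logit pi_gi = a + b * log(mu_gi)            (dropout probability)

where lambda_g is a log-normal baseline expression rate, s_i a log-normal
per-cell library-size factor and f_gt the log2 marker effect of gene g in
cell type t (zero off the marker blocks).  Dropout is mean-dependent:
lowly expressed genes are zeroed out more often, as in droplet data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from serocell.core import CellMeta, CountMatrix, GeneSet, SerocellError

logger = logging.getLogger(__name__)

#: Default per-site cell-type composition presets.  The primary-tumor and
#: metastatic presets reproduce the epithelial/lymphocyte shift observed in
#: high-grade serous ovarian cancer (primaries ~68.3% epithelial vs 11.1%
#: lymphocytes; omental metastases ~66.2% lymphocytes vs 10.5% epithelial);
#: normal ovary is mostly fibroblast/stromal with no epithelial cells.
COMPOSITION_PRESETS: dict[str, dict[str, float]] = {
    "primary": {
        "epithelial": 0.683,
        "tcell": 0.074,
        "bcell": 0.037,
        "myeloid": 0.080,
        "fibroblast": 0.050,
        "stromal": 0.046,
        "endothelial": 0.030,
    },
    "metastatic": {
        "epithelial": 0.105,
        "tcell": 0.497,
        "bcell": 0.165,
        "myeloid": 0.100,
        "fibroblast": 0.060,
        "stromal": 0.043,
        "endothelial": 0.030,
    },
    "normal": {
        "epithelial": 0.000,
        "tcell": 0.060,
        "bcell": 0.010,
        "myeloid": 0.050,
        "fibroblast": 0.450,
        "stromal": 0.350,
        "endothelial": 0.080,
    },
}

DEFAULT_CELL_TYPES = tuple(COMPOSITION_PRESETS["primary"])


@dataclass
class CellTypeSpec:
    """A simulated cell type: name, marker gene indices, marker log2 effect."""

    name: str
    marker_genes: list[int]
    marker_log2fc: float = 2.0


@dataclass
class SampleSpec:
    """A simulated sample with its site-dependent cell-type composition."""

    sample_id: str
    patient_id: str
    site: str
    grade: str
    n_cells: int
    composition: np.ndarray

    def __post_init__(self) -> None:
        self.composition = np.asarray(self.composition, dtype=float)
        if self.n_cells <= 0:
            raise SerocellError(f"sample {self.sample_id}: n_cells must be positive")
        if np.any(self.composition < 0):
            raise SerocellError(f"sample {self.sample_id}: negative composition entry")
        if abs(self.composition.sum() - 1.0) > 1e-8:
            raise SerocellError(
                f"sample {self.sample_id}: composition sums to "
                f"{self.composition.sum():.10f}, not 1"
            )


@dataclass
class CohortConfig:
    """Full parameterization of the synthetic cohort generator.

    Defaults are sized so that a cell detects a few hundred genes out of
    ``n_genes`` = 1500 (so the standard 200-genes-per-cell QC threshold
    binds on the low-library tail) with ~600 UMIs per cell.
    """

    n_genes: int = 1500
    cell_types: list[CellTypeSpec] = field(default_factory=list)
    samples: list[SampleSpec] = field(default_factory=list)
    #: (mu0, sigma0) of the log-normal baseline rate lambda_g.
    baseline_mean_logparams: tuple[float, float] = (float(np.log(0.3)), 1.2)
    #: NB dispersion theta; scalar shared by all genes, or one value per gene.
    dispersion: float | np.ndarray = 2.0
    #: (a, b) of the dropout model logit pi = a + b * log(mu).
    dropout_coeffs: tuple[float, float] = (-1.0, -1.0)
    #: (mean, sigma) of log s_i, the per-cell library-size factor.
    libsize_logparams: tuple[float, float] = (0.0, 0.35)
    #: Empty-droplet barcodes appended for knee-plot tests: (count, mean UMIs).
    ambient_barcodes: tuple[int, float] = (0, 20.0)
    seed: int = 0


@dataclass
class SyntheticTruth:
    """Generative ground truth emitted alongside a synthetic cohort."""

    cell_types: list[str]  # per real cell, aligned with CellMeta order
    lam: np.ndarray  # per-gene baseline rate lambda_g
    theta: np.ndarray  # per-gene dispersion
    effects: np.ndarray  # genes x cell-types log2 marker effects f_gt
    type_names: list[str]
    libsize: np.ndarray  # per real cell s_i
    dropout_coeffs: tuple[float, float]
    ambient_barcodes: list[str] = field(default_factory=list)
    spikes: list[tuple[str, float]] = field(default_factory=list)

    def marker_table(self) -> pd.DataFrame:
        """Long-format table of (gene index, cell type, log2 effect) markers."""
        rows = [
            (g, self.type_names[t], self.effects[g, t])
            for g, t in zip(*np.nonzero(self.effects))
        ]
        return pd.DataFrame(rows, columns=["gene_index", "cell_type", "log2fc"])


def default_cell_types(
    n_genes: int = 1500,
    names: tuple[str, ...] = DEFAULT_CELL_TYPES,
    markers_per_type: int = 25,
    marker_log2fc: float = 2.0,
) -> list[CellTypeSpec]:
    """Assign disjoint marker blocks at the start of the gene index range."""
    if markers_per_type * len(names) > n_genes:
        raise SerocellError("not enough genes for the requested marker blocks")
    return [
        CellTypeSpec(
            name,
            list(range(k * markers_per_type, (k + 1) * markers_per_type)),
            marker_log2fc,
        )
        for k, name in enumerate(names)
    ]


def preset_samples(
    layout: list[tuple[str, str, str, str, int]],
    type_names: list[str],
) -> list[SampleSpec]:
    """Build sample specs from (sample, patient, site, grade, n_cells) rows.

    Each sample's composition is the :data:`COMPOSITION_PRESETS` entry for
    its site, restricted and renormalized to ``type_names``.
    """
    specs = []
    for sample_id, patient_id, site, grade, n_cells in layout:
        preset = COMPOSITION_PRESETS[site]
        comp = np.array([preset.get(t, 0.0) for t in type_names])
        if comp.sum() <= 0:
            raise SerocellError(f"no preset mass on cell types for site {site}")
        specs.append(
            SampleSpec(sample_id, patient_id, site, grade, n_cells, comp / comp.sum())
        )
    return specs


def default_config(seed: int = 0, n_genes: int = 1500, cells_per_sample: int = 200) -> CohortConfig:
    """A four-sample, seven-cell-type cohort used as the packaged demo."""
    cell_types = default_cell_types(n_genes)
    names = [ct.name for ct in cell_types]
    samples = preset_samples(
        [
            ("HGA-P", "HGA", "primary", "HGSOC", cells_per_sample),
            ("HGA-M", "HGA", "metastatic", "HGSOC", cells_per_sample),
            ("LGA-P", "LGA", "primary", "LGSOC", cells_per_sample),
            ("NRM-N", "NRM", "normal", "normal", cells_per_sample),
        ],
        names,
    )
    return CohortConfig(n_genes=n_genes, cell_types=cell_types, samples=samples, seed=seed)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def zinb_zero_prob(mu: np.ndarray, theta: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """P(count = 0) = pi + (1 - pi) * (theta / (theta + mu))**theta."""
    return pi + (1.0 - pi) * (theta / (theta + mu)) ** theta

def zinb_mean(mu, theta, pi):
    """E[count] = (1 - pi) * mu."""
    return (1.0 - pi) * mu

def zinb_var(mu, theta, pi):
    """Var[count] = (1 - pi) * mu * (1 + mu / theta + pi * mu)."""
    return (1.0 - pi) * mu * (1.0 + mu / theta + pi * mu)


def _draw_zinb(
    rng: np.random.Generator,
    mu: np.ndarray,
    theta: np.ndarray,
    a: float,
    b: float,
) -> np.ndarray:
    """Draw ZINB counts elementwise for a genes x cells mean matrix."""
    with np.errstate(divide="ignore"):
        pi = _sigmoid(a + b * np.log(np.maximum(mu, 1e-300)))
    p = theta / (theta + mu)
    counts = rng.negative_binomial(theta, p)
    dropped = rng.random(mu.shape) < pi
    counts[dropped] = 0
    return counts


def _dispersion_vector(config: CohortConfig) -> np.ndarray:
    theta = np.asarray(config.dispersion, dtype=float)
    if theta.ndim == 0:
        theta = np.full(config.n_genes, float(theta))
    if theta.shape != (config.n_genes,):
        raise SerocellError("dispersion must be scalar or one value per gene")
    if np.any(theta <= 0):
        raise SerocellError("dispersion must be positive")
    return theta


def generate_cohort(
    config: CohortConfig,
) -> tuple[CountMatrix, list[CellMeta], SyntheticTruth]:
    """Generate a cohort of UMI counts with metadata and ground truth.

    Deterministic given ``config.seed``.  Ambient (empty-droplet) barcodes,
    if requested, are appended as extra matrix columns with no metadata
    record; their names are listed in ``truth.ambient_barcodes``.
    """
    if not config.cell_types:
        raise SerocellError("config.cell_types is empty")
    if not config.samples:
        raise SerocellError("config.samples is empty")
    rng = np.random.default_rng(config.seed)
    theta = _dispersion_vector(config)
    mu0, sd0 = config.baseline_mean_logparams
    lam = rng.lognormal(mu0, sd0, config.n_genes)
    type_names = [ct.name for ct in config.cell_types]
    effects = np.zeros((config.n_genes, len(type_names)))
    for k, ct in enumerate(config.cell_types):
        effects[np.asarray(ct.marker_genes, dtype=int), k] = ct.marker_log2fc

    a, b = config.dropout_coeffs
    ls_mean, ls_sd = config.libsize_logparams
    blocks: list[sp.csc_matrix] = []
    barcodes: list[str] = []
    meta: list[CellMeta] = []
    truth_types: list[str] = []
    libsizes: list[np.ndarray] = []
    for spec in config.samples:
        if len(spec.composition) != len(type_names):
            raise SerocellError(
                f"sample {spec.sample_id}: composition length {len(spec.composition)} "
                f"!= {len(type_names)} cell types"
            )
        types = rng.choice(len(type_names), size=spec.n_cells, p=spec.composition)
        s = rng.lognormal(ls_mean, ls_sd, spec.n_cells)
        mu = s[None, :] * lam[:, None] * 2.0 ** effects[:, types]
        block = _draw_zinb(rng, mu, theta[:, None], a, b)
        blocks.append(sp.csc_matrix(block))
        for i in range(spec.n_cells):
            barcodes.append(f"{spec.sample_id}:C{i:04d}")
            truth_types.append(type_names[types[i]])
        libsizes.append(s)
        for i, bc in enumerate(barcodes[-spec.n_cells :]):
            meta.append(
                CellMeta(
                    bc,
                    spec.sample_id,
                    spec.patient_id,
                    spec.site,
                    spec.grade,
                    int(block[:, i].sum()),
                    int((block[:, i] > 0).sum()),
                )
            )

    ambient_names: list[str] = []
    n_ambient, ambient_mean = config.ambient_barcodes
    if n_ambient > 0:
        # empty droplets: sparse Poisson soup proportional to lambda_g
        soup = lam / lam.sum()
        amb = rng.poisson(ambient_mean * soup[:, None], (config.n_genes, n_ambient))
        blocks.append(sp.csc_matrix(amb))
        ambient_names = [f"AMB:C{i:04d}" for i in range(n_ambient)]
        barcodes.extend(ambient_names)

    counts = CountMatrix(_gene_names(config.n_genes), barcodes, sp.hstack(blocks))
    truth = SyntheticTruth(
        cell_types=truth_types,
        lam=lam,
        theta=theta,
        effects=effects,
        type_names=type_names,
        libsize=np.concatenate(libsizes),
        dropout_coeffs=(a, b),
        ambient_barcodes=ambient_names,
    )
    return counts, meta, truth


def generate_null_pair(
    config: CohortConfig,
    n_per_group: int,
) -> tuple[CountMatrix, np.ndarray, SyntheticTruth]:
    """Two groups of cells drawn from identical parameters (no cell types).

    Any differential-expression signal between the returned groups is a
    false positive by construction; used to calibrate the type-I error of
    the ZINB likelihood-ratio test.  Returns ``(counts, labels, truth)``
    with ``labels`` an integer array of 0/1 group assignments.
    """
    if n_per_group < 2:
        raise SerocellError("need at least 2 cells per group")
    null_type = [CellTypeSpec("null", [], 0.0)]
    samples = [
        SampleSpec("NULL-A", "NULL", "primary", "HGSOC", n_per_group, np.array([1.0])),
        SampleSpec("NULL-B", "NULL", "primary", "HGSOC", n_per_group, np.array([1.0])),
    ]
    cfg = replace(config, cell_types=null_type, samples=samples, ambient_barcodes=(0, 0.0))
    counts, meta, truth = generate_cohort(cfg)
    labels = np.array([0] * n_per_group + [1] * n_per_group)
    return counts, labels, truth


def spike_signature(
    counts: CountMatrix,
    meta: list[CellMeta],
    truth: SyntheticTruth,
    gene_set: GeneSet,
    target_group: str | list[str],
    log2_effect: float,
    seed: int = 0,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Regenerate a gene set's counts in a target group with boosted means.

    ``target_group`` is a sample id or an explicit list of barcodes.  The
    affected entries are redrawn from the generative model with means
    multiplied by ``2**log2_effect``; everything else is untouched.
    Deterministic given ``seed``.  Returns a new matrix and updated truth.
    """
    barcode_pos = {bc: j for j, bc in enumerate(counts.barcodes)}
    if isinstance(target_group, str):
        target = [m.barcode for m in meta if m.sample_id == target_group]
        if not target:
            raise SerocellError(f"unknown target group {target_group!r}")
    else:
        target = list(target_group)
        if not target:
            raise SerocellError("empty target group")
        missing = [bc for bc in target if bc not in barcode_pos]
        if missing:
            raise SerocellError(f"unknown barcodes in target group: {missing[:3]}")
    gene_pos = {g: i for i, g in enumerate(counts.genes)}
    unknown = [g for g in gene_set.genes if g not in gene_pos]
    if unknown:
        raise SerocellError(f"unknown genes in {gene_set.name}: {unknown[:3]}")

    gidx = np.array([gene_pos[g] for g in gene_set.genes])
    cidx = np.array([barcode_pos[bc] for bc in target])
    meta_pos = {m.barcode: k for k, m in enumerate(meta)}
    type_idx = np.array(
        [truth.type_names.index(truth.cell_types[meta_pos[bc]]) for bc in target]
    )
    s = truth.libsize[[meta_pos[bc] for bc in target]]
    mu = (
        s[None, :]
        * truth.lam[gidx, None]
        * 2.0 ** truth.effects[np.ix_(gidx, type_idx)]
        * 2.0**log2_effect
    )
    rng = np.random.default_rng(seed)
    a, b = truth.dropout_coeffs
    block = _draw_zinb(rng, mu, truth.theta[gidx, None], a, b)

    dense = counts.counts.tolil(copy=True)
    for r, g in enumerate(gidx):
        for c, j in enumerate(cidx):
            dense[g, j] = block[r, c]
    new_counts = CountMatrix(counts.genes, counts.barcodes, dense.tocsc())
    new_truth = replace(truth, spikes=truth.spikes + [(gene_set.name, log2_effect)])
    return new_counts, new_truth


def write_truth(truth: SyntheticTruth, path) -> None:
    """Serialize per-gene ground-truth parameters as TSV."""
    df = pd.DataFrame(
        {
            "gene_index": np.arange(truth.lam.size),
            "lambda": truth.lam,
            "theta": truth.theta,
        }
    )
    for k, name in enumerate(truth.type_names):
        df[f"log2fc_{name}"] = truth.effects[:, k]
    df.to_csv(path, sep="\t", index=False)
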