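"""Core containers, standard-format I/O and knee-plot cell calling.

Conventions used throughout the package: genes are rows and cells are
columns; Matrix Market files are 1-based (the format standard) while all
in-memory coordinates are 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Anatomical origin labels allowed in per-cell metadata.
SITES = ("primary", "metastatic", "normal")
#: Tumor grade / histology labels allowed in per-cell metadata.
GRADES = ("HGSOC", "HGSOC-F", "LGSOC", "benign", "peritoneal", "normal")


class SerocellError(Exception):
    """Base class for errors raised by serocell."""


class DimensionMismatchError(SerocellError):
    """Matrix dimensions disagree with the gene/barcode identifier lists."""


class NoKneeError(SerocellError):
    """The barcode rank curve is degenerate and has no knee point."""


class AllFilteredError(SerocellError):
    """A QC filter removed every gene or every cell."""


@dataclass
class CountMatrix:
    """Sparse genes x cells matrix of non-negative integer UMI counts.

    Parameters
    ----------
    genes
        Unique gene symbols, one per matrix row.
    barcodes
        Unique cell barcodes, one per matrix column.
    counts
        ``scipy.sparse`` matrix of shape ``(len(genes), len(barcodes))``
        holding deduplicated transcript (UMI) counts.
    """

    genes: list[str]
    barcodes: list[str]
    counts: sp.spmatrix

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.barcodes = list(self.barcodes)
        self.counts = sp.csc_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise DimensionMismatchError(
                f"matrix is {self.counts.shape} but identifier lists imply "
                f"({len(self.genes)}, {len(self.barcodes)})"
            )
        if len(set(self.genes)) != len(self.genes):
            raise SerocellError("duplicate gene symbols")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise SerocellError("duplicate cell barcodes")
        data = self.counts.data
        if data.size and (data.min() < 0 or np.any(data != np.round(data))):
            raise SerocellError("counts must be non-negative integers")
        self.counts = self.counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def total_umis(self) -> np.ndarray:
        """Per-cell column sums (genic UMIs per barcode)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Per-cell number of genes with a nonzero count."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def cells_per_gene(self) -> np.ndarray:
        """Per-gene number of cells with a nonzero count."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def subset(
        self,
        gene_idx: np.ndarray | list[int] | None = None,
        cell_idx: np.ndarray | list[int] | None = None,
    ) -> "CountMatrix":
        """Return a new matrix restricted to the given row/column indices."""
        gi = np.arange(self.n_genes) if gene_idx is None else np.asarray(gene_idx)
        ci = np.arange(self.n_cells) if cell_idx is None else np.asarray(cell_idx)
        return CountMatrix(
            [self.genes[i] for i in gi],
            [self.barcodes[i] for i in ci],
            self.counts[gi][:, ci],
        )


@dataclass
class CellMeta:
    """Per-cell sample annotation plus QC covariates and assigned labels."""

    barcode: str
    sample_id: str
    patient_id: str
    site: str
    grade: str
    total_umis: int
    n_genes_detected: int
    cluster: int | None = None
    cell_type: str | None = None

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise SerocellError(f"unknown site {self.site!r}; expected one of {SITES}")
        if self.grade not in GRADES:
            raise SerocellError(f"unknown grade {self.grade!r}; expected one of {GRADES}")


def build_cell_meta(
    counts: CountMatrix,
    sample_info: dict[str, tuple[str, str, str, str]],
) -> list[CellMeta]:
    """Derive :class:`CellMeta` records from a count matrix.

    ``sample_info`` maps each barcode to ``(sample_id, patient_id, site,
    grade)``.  QC covariates (total UMIs, genes detected) are computed from
    the matrix columns.  Barcodes missing from ``sample_info`` are skipped.
    """
    totals = counts.total_umis()
    ngenes = counts.genes_detected()
    meta = []
    for j, bc in enumerate(counts.barcodes):
        if bc not in sample_info:
            continue
        sample_id, patient_id, site, grade = sample_info[bc]
        meta.append(
            CellMeta(bc, sample_id, patient_id, site, grade, int(totals[j]), int(ngenes[j]))
        )
    return meta


def meta_to_frame(meta: list[CellMeta]) -> pd.DataFrame:
    """Tabulate a list of :class:`CellMeta` as a DataFrame indexed by barcode."""
    return pd.DataFrame([vars(m) for m in meta]).set_index("barcode")


def read_cell_meta(path: str | Path) -> list[CellMeta]:
    """Read per-cell metadata from a TSV written by :func:`write_cell_meta`."""
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str})
    meta = []
    for row in df.itertuples(index=False):
        cluster = None if pd.isna(getattr(row, "cluster", None)) else int(row.cluster)
        cell_type = getattr(row, "cell_type", None)
        if isinstance(cell_type, float) and np.isnan(cell_type):
            cell_type = None
        meta.append(
            CellMeta(
                row.barcode,
                row.sample_id,
                row.patient_id,
                row.site,
                row.grade,
                int(row.total_umis),
                int(row.n_genes_detected),
                cluster,
                cell_type,
            )
        )
    return meta


def write_cell_meta(meta: list[CellMeta], path: str | Path) -> None:
    pd.DataFrame([vars(m) for m in meta]).to_csv(path, sep="\t", index=False)


@dataclass
class GeneSet:
    """A named, duplicate-free list of gene symbols."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise SerocellError(f"gene set {self.name!r} is empty")
        seen: dict[str, None] = {}
        deduped = [g for g in self.genes if not (g in seen or seen.setdefault(g, None))]
        if len(deduped) != len(self.genes):
            logger.warning(
                "gene set %s: collapsed %d duplicate symbols",
                self.name,
                len(self.genes) - len(deduped),
            )
        self.genes = deduped

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class BarcodeRankCurve:
    """Barcode UMI totals sorted in non-increasing order (rank -> count)."""

    counts: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.size and np.any(np.diff(c) > 0):
            raise SerocellError("rank curve counts must be non-increasing")
        if c.size and c.min() <= 0:
            raise SerocellError("rank curve counts must be positive")
        self.counts = c

    @classmethod
    def from_matrix(cls, counts: CountMatrix) -> "BarcodeRankCurve":
        """Rank curve of per-barcode genic UMI totals; zero barcodes dropped."""
        totals = counts.total_umis()
        totals = totals[totals > 0]
        return cls(np.sort(totals)[::-1])


def knee_threshold(curve: BarcodeRankCurve) -> tuple[int, int]:
    """Locate the knee of a barcode rank plot and return a UMI threshold.

    The knee is the rank with maximum perpendicular distance to the chord
    joining the first and last points of the log10(rank) vs log10(count)
    curve.  Ties are broken toward the larger rank so that more barcodes
    are retained.  Returns ``(umi_threshold, n_retained)`` where retained
    barcodes are those with ``count >= umi_threshold``.

    Raises
    ------
    NoKneeError
        If the curve has fewer than 10 barcodes or all counts are equal,
        in which case no inflection exists and the caller must decide.
    """
    c = curve.counts
    if c.size < 10:
        raise NoKneeError(f"need at least 10 barcodes, got {c.size}")
    if c.max() == c.min():
        raise NoKneeError("all barcode counts equal; curve has no knee")
    x = np.log10(np.arange(1, c.size + 1, dtype=float))
    y = np.log10(c.astype(float))
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    # perpendicular distance of each point to the first-to-last chord
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / norm
    best = dist.max()
    knee = int(np.flatnonzero(dist == best)[-1])
    threshold = int(c[knee])
    retained = int((c >= threshold).sum())
    logger.info(
        "knee at rank %d (distance %.4f): threshold %d UMIs, %d barcodes retained",
        knee + 1,
        best,
        threshold,
        retained,
    )
    return threshold, retained


# ---------------------------------------------------------------------------
# File I/O


def read_counts(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> CountMatrix:
    """Read a genes x cells UMI matrix.

    ``matrix_path`` may be Matrix Market coordinate format (``.mtx``) or a
    dense TSV with one row per gene.  Gene and barcode lists are plain text,
    one identifier per line, and must match the matrix dimensions.
    """
    genes = _read_lines(genes_path)
    barcodes = _read_lines(barcodes_path)
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        mat = scipy.io.mmread(str(matrix_path))
    else:
        mat = pd.read_csv(matrix_path, sep="\t", header=None).to_numpy()
    mat = sp.csc_matrix(mat)
    if mat.shape != (len(genes), len(barcodes)):
        raise DimensionMismatchError(
            f"{matrix_path.name} is {mat.shape} but gene/barcode lists imply "
            f"({len(genes)}, {len(barcodes)})"
        )
    return CountMatrix(genes, barcodes, mat)


def write_counts(
    counts: CountMatrix,
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    """Write a matrix in Matrix Market (or dense TSV) form with id lists.

    Round-trips bit-exactly through :func:`read_counts`.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(counts.counts), field="integer")
    else:
        pd.DataFrame(counts.counts.toarray()).to_csv(
            matrix_path, sep="\t", header=False, index=False
        )
    _write_lines(genes_path, counts.genes)
    _write_lines(barcodes_path, counts.barcodes)


def read_gene_sets(gmt_path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, tab-separated symbols).

    The description field is discarded; duplicate symbols within a line are
    collapsed with a logged warning.
    """
    sets = []
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SerocellError(
                    f"{gmt_path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene (got {len(fields)} fields)"
                )
            sets.append(GeneSet(fields[0], fields[2:]))
    if not sets:
        raise SerocellError(f"{gmt_path}: empty GMT file")
    return sets


def write_gene_sets(sets: list[GeneSet], gmt_path: str | Path) -> None:
    with open(gmt_path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *gs.genes]) + "\n")


def _read_lines(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _write_lines(path: str | Path, lines: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
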