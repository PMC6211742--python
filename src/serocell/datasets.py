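"""Loaders for the small data tables and gene-set fixtures shipped with the
package: the transcribed description of the motivating serous ovarian tumor
cohort (nine patients, fourteen samples), its per-group TCGA-subtype score
matrices and biomarker statistics, the cell-type marker panels, and standard
cell-cycle phase gene lists.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from serocell.core import GeneSet, read_gene_sets
from serocell.subtype import ScoreMatrix


def _data_path(name: str):
    return resources.files("serocell.data").joinpath(name)


def patient_table() -> pd.DataFrame:
    """Per-patient clinical summary: age at diagnosis, neoplasm type, stage."""
    with resources.as_file(_data_path("study_patients.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def sample_table() -> pd.DataFrame:
    """Per-sample description: patient, site, grade and cells captured."""
    with resources.as_file(_data_path("study_samples.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def subtype_score_tables() -> tuple[ScoreMatrix, ScoreMatrix]:
    """Transcribed per-sample (14x4) and per-cluster (16x4) subtype scores."""
    with resources.as_file(_data_path("subtype_scores.tsv")) as p:
        df = pd.read_csv(p, sep="\t", index_col="group")
    samples = ScoreMatrix(df[df["level"] == "sample"].drop(columns="level"))
    clusters = ScoreMatrix(df[df["level"] == "cluster"].drop(columns="level"))
    return samples, clusters


def reference_biomarker_table() -> pd.DataFrame:
    """Transcribed biomarker statistics (fold change, detection fractions, p)."""
    with resources.as_file(_data_path("reference_biomarkers.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def marker_panels() -> list[GeneSet]:
    """Cell-type marker panels (epithelial, lymphocyte, endothelial, ...)."""
    with resources.as_file(_data_path("marker_panels.gmt")) as p:
        return read_gene_sets(p)


def cell_cycle_gene_sets() -> tuple[GeneSet, GeneSet]:
    """The widely used S-phase (43-gene) and G2/M (54-gene) lists."""
    with resources.as_file(_data_path("cell_cycle.gmt")) as p:
        sets = {gs.name: gs for gs in read_gene_sets(p)}
    return sets["S"], sets["G2M"]
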