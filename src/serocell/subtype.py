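"""Gene-signature scoring of cell groups against the four TCGA HGSOC
expression subtypes (differentiated, immunoreactive, mesenchymal,
proliferative) and threshold classification.

A group's score for a signature is the mean, over the signature's genes,
of the group's average normalized expression relative to the average over
all cells — a relative-enrichment ratio centered at 1.  Classification
pools every score of every supplied matrix (e.g. the per-sample and
per-cluster matrices together) and calls a group a subtype only when its
score strictly exceeds the pooled mean plus two standard deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from serocell.core import GeneSet, SerocellError
from serocell.preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)

SUBTYPE_NAMES = ("differentiated", "immunoreactive", "mesenchymal", "proliferative")


@dataclass
class ScoreMatrix:
    """Groups x signatures matrix of relative-enrichment scores."""

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise SerocellError("signature scores must be finite and non-negative")


@dataclass
class SubtypeCall:
    """A group's subtype assignment under the mean + 2 SD rule."""

    group: str
    subtype: str  # one of the signature names, or "unclassified"
    score: float
    threshold: float

    def __post_init__(self) -> None:
        if self.subtype != "unclassified" and not self.score > self.threshold:
            raise SerocellError("assigned call must have score > threshold")


def score_groups(
    norm: NormalizedMatrix,
    grouping: np.ndarray | list,
    signatures: list[GeneSet],
) -> ScoreMatrix:
    """Score each cell group against each signature gene set.

    ``grouping`` assigns every cell (matrix column) a group label.  The
    entry for (group, signature) is the mean over the signature's genes of
    group-mean expression divided by global-mean expression; genes with
    zero global mean are skipped with a warning.
    """
    labels = np.asarray(grouping)
    if labels.shape != (norm.n_cells,):
        raise SerocellError("grouping must assign a label to every cell")
    gene_pos = {g: i for i, g in enumerate(norm.genes)}
    global_mean = norm.values.mean(axis=1)

    sig_idx: list[np.ndarray] = []
    for sig in signatures:
        idx = np.array([gene_pos[g] for g in sig.genes if g in gene_pos], dtype=int)
        usable = idx[global_mean[idx] > 0]
        if usable.size < idx.size:
            logger.warning(
                "signature %s: skipped %d genes with zero global mean",
                sig.name,
                idx.size - usable.size,
            )
        if usable.size == 0:
            raise SerocellError(f"signature {sig.name!r} has no usable genes")
        sig_idx.append(usable)

    groups = list(dict.fromkeys(labels.tolist()))
    rows = {}
    for grp in groups:
        members = labels == grp
        if not members.any():
            raise SerocellError(f"empty group {grp!r}")
        grp_mean = norm.values[:, members].mean(axis=1)
        rows[grp] = [
            float((grp_mean[idx] / global_mean[idx]).mean()) for idx in sig_idx
        ]
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=[s.name for s in signatures]
    )
    return ScoreMatrix(df)


def classify_subtypes(
    matrices: list[ScoreMatrix],
    n_sd: float = 2.0,
    ddof: int = 0,
) -> list[SubtypeCall]:
    """Classify every group of every score matrix with a pooled threshold.

    All entries of all supplied matrices are pooled; the threshold is the
    pooled mean plus ``n_sd`` pooled standard deviations (population SD by
    default, sample SD with ``ddof=1``).  A group is assigned the argmax
    signature among those strictly above the threshold, or
    ``"unclassified"`` when none exceed it.
    """
    if not matrices:
        raise SerocellError("need at least one score matrix")
    columns = list(matrices[0].scores.columns)
    for m in matrices[1:]:
        if list(m.scores.columns) != columns:
            raise SerocellError("score matrices have inconsistent signature columns")
    pooled = np.concatenate([m.scores.to_numpy(dtype=float).ravel() for m in matrices])
    if pooled.size < 2:
        raise SerocellError("need at least 2 pooled entries to define an SD")
    thr = float(pooled.mean() + n_sd * pooled.std(ddof=ddof))

    calls: list[SubtypeCall] = []
    for m in matrices:
        for group, row in m.scores.iterrows():
            vals = row.to_numpy(dtype=float)
            best = float(vals.max())
            if best > thr:
                calls.append(SubtypeCall(str(group), columns[int(vals.argmax())], best, thr))
            else:
                calls.append(SubtypeCall(str(group), "unclassified", best, thr))
    return calls
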