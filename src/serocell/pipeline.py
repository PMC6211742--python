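"""End-to-end pipeline orchestration: cell calling through subtype calls.

Stages run in the order of the underlying workflow — cell-calling,
qc-filter, normalize-regress, variable-genes, pca-elbow, cluster,
annotate, diffexp, composition, subtype — each writing TSV outputs under
the run directory and appending a record to the run manifest.  A global
seed fans out to fixed per-stage seeds, so a run is bit-reproducible from
its config and seed alone.
"""

from __future__ import annotations

import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import serocell
from serocell import cluster as cl
from serocell import composition as cmp
from serocell import diffexp as de
from serocell import preprocess as pp
from serocell import subtype as st
from serocell import synthetic as syn
from serocell.core import (
    BarcodeRankCurve,
    GeneSet,
    NoKneeError,
    SerocellError,
    knee_threshold,
    read_cell_meta,
    read_counts,
    read_gene_sets,
    write_cell_meta,
    write_counts,
    write_gene_sets,
)

logger = logging.getLogger(__name__)

STAGES = (
    "cell-calling",
    "qc-filter",
    "normalize-regress",
    "variable-genes",
    "pca-elbow",
    "cluster",
    "annotate",
    "diffexp",
    "composition",
    "subtype",
)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "inputs": {},
    "gene_sets": {},
    "cell_calling": {"enabled": True},
    "qc": {"min_cells": 3, "min_genes": 200},
    "normalize": {"scale_factor": 10000.0},
    "cell_cycle": {"n_bins": 25, "n_ctrl": 50},
    "scale": {"clip": 10.0},
    "variable_genes": {"n_bins": 20, "z_cutoff": 1.0, "max_genes": 2000},
    "pca": {"n_components": 30, "k_override": None},
    "cluster": {"k_neighbors": 20, "prune": 1 / 15, "resolution": 1.0},
    "annotate": {"min_frac": 0.25},
    "diffexp": {
        "min_pct": 0.1,
        "adjust": "bonferroni",
        "alpha": 0.05,
        "min_lfc": 1.0,
        "min_pct_in": 0.5,
        "min_pct_diff": 0.5,
        "max_genes": 100,
    },
    "composition": {"n_groups": 2},
    "subtype": {"n_sd": 2.0, "ddof": 0},
    "plots": True,
}


class PipelineError(SerocellError):
    """A stage failed; the message names the stage."""


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)


def _merged_config(config: dict) -> dict:
    merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in config.items():
        if isinstance(v, dict) and isinstance(merged.get(k), dict):
            merged[k].update(v)
        else:
            merged[k] = v
    return merged


def load_config(config_path: str | Path) -> dict:
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    cfg = _merged_config(cfg)
    # input paths are relative to the config file
    base = Path(config_path).parent
    for section in ("inputs", "gene_sets"):
        for key, val in cfg.get(section, {}).items():
            if val is not None:
                cfg[section][key] = str((base / val).resolve())
    return cfg


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Run every stage on the configured inputs; returns the run manifest.

    ``config`` is a YAML path or an already-merged config dict.  On a
    stage error a :class:`PipelineError` naming the stage is raised after
    the partial manifest is written.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = _merged_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "version": serocell.__version__,
        "seed": seed,
        "config": config,
        "stages": [],
    }

    state: dict = {}
    try:
        for name in STAGES:
            t0 = time.perf_counter()
            record = _run_stage(name, config, state, out, seed)
            record["name"] = name
            record["elapsed_s"] = round(time.perf_counter() - t0, 3)
            manifest["stages"].append(record)
            logger.info("stage %s done in %.2fs", name, record["elapsed_s"])
    except Exception as exc:
        _write_manifest(manifest, out)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {name}: {exc}") from exc
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False, default_flow_style=False)


def _run_stage(name: str, config: dict, state: dict, out: Path, seed: int) -> dict:
    sseed = stage_seed(seed, name)
    if name == "cell-calling":
        inputs = config["inputs"]
        for key in ("matrix", "genes", "barcodes", "meta"):
            if key not in inputs or not Path(inputs[key]).exists():
                raise PipelineError(f"stage cell-calling: missing input {key!r}")
        counts = read_counts(inputs["matrix"], inputs["genes"], inputs["barcodes"])
        meta = read_cell_meta(inputs["meta"])
        n_in = counts.n_cells
        if config["cell_calling"]["enabled"]:
            curve = BarcodeRankCurve.from_matrix(counts)
            try:
                threshold, _ = knee_threshold(curve)
                keep = np.flatnonzero(counts.total_umis() >= threshold)
                counts = counts.subset(cell_idx=keep)
            except NoKneeError:
                logger.warning("no knee in barcode rank curve; keeping all barcodes")
                threshold = 0
        else:
            threshold = 0
        called = set(counts.barcodes)
        meta = [m for m in meta if m.barcode in called]
        with_meta = {m.barcode for m in meta}
        keep = [j for j, bc in enumerate(counts.barcodes) if bc in with_meta]
        counts = counts.subset(cell_idx=keep)
        state["counts"], state["meta"] = counts, meta
        return {
            "params": {"umi_threshold": int(threshold)},
            "n_in": int(n_in),
            "n_out": int(counts.n_cells),
        }

    if name == "qc-filter":
        counts, report = pp.filter_matrix(state["counts"], **config["qc"])
        retained = set(counts.barcodes)
        state["meta"] = [m for m in state["meta"] if m.barcode in retained]
        n_in = state["counts"].n_cells
        state["counts"] = counts
        return {"params": report, "n_in": int(n_in), "n_out": int(counts.n_cells)}

    if name == "normalize-regress":
        counts = state["counts"]
        norm = pp.log_normalize(counts, config["normalize"]["scale_factor"])
        s_set, g2m_set = _load_cell_cycle(config)
        scores = pp.cell_cycle_score(
            norm, s_set, g2m_set, seed=sseed, **config["cell_cycle"]
        )
        regressed = pp.regress_covariates(
            norm, counts.total_umis(), scores.s_score, scores.g2m_score
        )
        scaled = pp.scale_and_clip(regressed, config["scale"]["clip"])
        state["lognorm"], state["scaled"], state["cc"] = norm, scaled, scores
        pd.DataFrame(
            {"barcode": norm.barcodes, "s_score": scores.s_score, "g2m_score": scores.g2m_score}
        ).to_csv(out / "cell_cycle_scores.tsv", sep="\t", index=False)
        return {
            "params": {**config["normalize"], **config["cell_cycle"]},
            "n_in": int(counts.n_cells),
            "n_out": int(counts.n_cells),
            "outputs": ["cell_cycle_scores.tsv"],
        }

    if name == "variable-genes":
        hvg = pp.select_variable_genes(state["lognorm"], **config["variable_genes"])
        if not hvg:
            raise PipelineError("stage variable-genes: no variable genes selected")
        state["hvg"] = hvg
        (out / "variable_genes.txt").write_text("\n".join(hvg) + "\n")
        return {
            "params": config["variable_genes"],
            "n_in": int(state["lognorm"].n_genes),
            "n_out": len(hvg),
            "outputs": ["variable_genes.txt"],
        }

    if name == "pca-elbow":
        scaled = state["scaled"]
        gene_pos = {g: i for i, g in enumerate(scaled.genes)}
        idx = [gene_pos[g] for g in state["hvg"]]
        sub = pp.NormalizedMatrix(
            [scaled.genes[i] for i in idx],
            list(scaled.barcodes),
            scaled.values[idx],
            scaled.provenance,
        )
        n_comp = min(config["pca"]["n_components"], len(idx), scaled.n_cells)
        pca = cl.pca_embed(sub, n_comp)
        k = config["pca"]["k_override"] or cl.select_elbow(pca.variance_fractions)
        k = max(k, 2)
        state["pcs"] = pca.scores[:, :k]
        np.savetxt(out / "pca_scores.tsv", pca.scores, delimiter="\t")
        return {
            "params": {"n_components": n_comp, "k_selected": int(k)},
            "n_in": len(idx),
            "n_out": int(k),
            "outputs": ["pca_scores.tsv"],
        }

    if name == "cluster":
        res = cl.snn_cluster(state["pcs"], seed=sseed, **config["cluster"])
        coords = cl.tsne_embed(state["pcs"], seed=sseed)
        state["clusters"], state["tsne"] = res, coords
        df = pd.DataFrame(
            {
                "barcode": state["counts"].barcodes,
                "cluster": res.labels,
                "tsne1": coords[:, 0],
                "tsne2": coords[:, 1],
            }
        )
        df.to_csv(out / "clusters.tsv", sep="\t", index=False)
        return {
            "params": {**config["cluster"], "modularity": round(res.modularity, 6)},
            "n_in": int(len(res.labels)),
            "n_out": int(res.n_clusters),
            "outputs": ["clusters.tsv"],
        }

    if name == "annotate":
        panels = read_gene_sets(config["gene_sets"]["markers"])
        sites = [m.site for m in state["meta"]]
        res = cl.annotate_clusters(
            state["lognorm"],
            state["clusters"],
            panels,
            min_frac=config["annotate"]["min_frac"],
            sites=sites,
        )
        state["clusters"] = res
        for m, lab in zip(state["meta"], res.labels):
            m.cluster = int(lab)
            m.cell_type = res.annotations[int(lab)]
        write_cell_meta(state["meta"], out / "annotated_cells.tsv")
        if config.get("plots"):
            _plot_tsne(state["tsne"], res, out / "tsne.png")
        return {
            "params": {"labels": res.annotations},
            "n_in": int(res.n_clusters),
            "n_out": int(res.n_clusters),
            "outputs": ["annotated_cells.tsv"],
        }

    if name == "diffexp":
        cfg = config["diffexp"]
        counts, norm = state["counts"], state["lognorm"]
        gene_pos = {g: i for i, g in enumerate(counts.genes)}
        de_genes = [g for g in state["hvg"][: cfg["max_genes"]]]
        sub = counts.subset(gene_idx=[gene_pos[g] for g in de_genes])
        res = state["clusters"]
        all_results = []
        for k in range(res.n_clusters):
            in_mask = res.labels == k
            if in_mask.sum() < 3 or (~in_mask).sum() < 3:
                continue
            results, _ = de.lrt_de(
                sub, norm, in_mask, ~in_mask, min_pct=cfg["min_pct"], adjust=cfg["adjust"]
            )
            markers = de.biomarker_filter(
                results,
                alpha=cfg["alpha"],
                min_lfc=cfg["min_lfc"],
                min_pct=cfg["min_pct_in"],
                min_pct_diff=cfg["min_pct_diff"],
            )
            marker_genes = {r.gene for r in markers}
            for r in results:
                all_results.append(
                    {
                        "cluster": k,
                        "label": res.annotations.get(k, ""),
                        "gene": r.gene,
                        "avg_log2fc": r.avg_log2fc,
                        "pct_in": r.pct_in,
                        "pct_out": r.pct_out,
                        "p_raw": r.p_raw,
                        "p_adj": r.p_adj,
                        "biomarker": r.gene in marker_genes,
                    }
                )
        pd.DataFrame(all_results).to_csv(out / "diffexp.tsv", sep="\t", index=False)
        return {
            "params": cfg,
            "n_in": len(de_genes),
            "n_out": len(all_results),
            "outputs": ["diffexp.tsv"],
        }

    if name == "composition":
        table = cmp.composition_table(state["meta"])
        _, newick, flat = cmp.cluster_samples(
            table, n_groups=min(config["composition"]["n_groups"], table.counts.shape[0])
        )
        table.counts.to_csv(out / "composition_counts.tsv", sep="\t")
        table.proportions.to_csv(out / "composition_proportions.tsv", sep="\t")
        (out / "sample_dendrogram.nwk").write_text(newick + "\n")
        fisher_rows = []
        for sample in table.counts.index:
            for ctype in table.counts.columns:
                try:
                    odds, p = cmp.fisher_enrichment(table, ctype, sample)
                except SerocellError:
                    continue
                fisher_rows.append(
                    {"sample": sample, "cell_type": ctype, "odds_ratio": odds, "p": p}
                )
        pd.DataFrame(fisher_rows).to_csv(out / "fisher_enrichment.tsv", sep="\t", index=False)
        state["composition"] = table
        if config.get("plots"):
            _plot_composition(table, out / "composition.png")
        return {
            "params": config["composition"],
            "n_in": int(table.counts.to_numpy().sum()),
            "n_out": int(table.counts.shape[0]),
            "outputs": [
                "composition_counts.tsv",
                "composition_proportions.tsv",
                "sample_dendrogram.nwk",
                "fisher_enrichment.tsv",
            ],
        }

    if name == "subtype":
        sig_path = config["gene_sets"].get("subtypes")
        if sig_path is None:
            logger.warning("no subtype signatures configured; stage skipped")
            return {"params": {}, "n_in": 0, "n_out": 0}
        signatures = read_gene_sets(sig_path)
        norm = state["lognorm"]
        res = state["clusters"]
        samples = np.array([m.sample_id for m in state["meta"]])
        by_sample = st.score_groups(norm, samples, signatures)
        labels = np.array(
            [f"{lab}:{res.annotations.get(lab, lab)}" for lab in res.labels]
        )
        by_cluster = st.score_groups(norm, labels, signatures)
        calls = st.classify_subtypes(
            [by_sample, by_cluster],
            n_sd=config["subtype"]["n_sd"],
            ddof=config["subtype"]["ddof"],
        )
        by_sample.scores.to_csv(out / "subtype_scores_samples.tsv", sep="\t")
        by_cluster.scores.to_csv(out / "subtype_scores_clusters.tsv", sep="\t")
        pd.DataFrame([vars(c) for c in calls]).to_csv(
            out / "subtype_calls.tsv", sep="\t", index=False
        )
        n_called = sum(c.subtype != "unclassified" for c in calls)
        return {
            "params": config["subtype"],
            "n_in": len(calls),
            "n_out": int(n_called),
            "outputs": [
                "subtype_scores_samples.tsv",
                "subtype_scores_clusters.tsv",
                "subtype_calls.tsv",
            ],
        }

    raise PipelineError(f"unknown stage {name}")


def _load_cell_cycle(config: dict) -> tuple[GeneSet, GeneSet]:
    path = config["gene_sets"].get("cell_cycle")
    if path is None:
        from serocell.datasets import cell_cycle_gene_sets

        return cell_cycle_gene_sets()
    sets = {gs.name: gs for gs in read_gene_sets(path)}
    return sets["S"], sets["G2M"]


def _plot_tsne(coords: np.ndarray, clusters, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for k in range(clusters.n_clusters):
        mask = clusters.labels == k
        ax.scatter(
            coords[mask, 0],
            coords[mask, 1],
            s=8,
            label=f"{k}: {clusters.annotations.get(k, '')}",
        )
    ax.set_xlabel("tSNE 1")
    ax.set_ylabel("tSNE 2")
    ax.legend(fontsize=7, markerscale=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_composition(table, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ax = table.proportions.plot.bar(stacked=True, figsize=(7, 4))
    ax.set_ylabel("proportion of cells")
    ax.legend(fontsize=7, bbox_to_anchor=(1.02, 1), loc="upper left")
    fig = ax.get_figure()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Demo fixture


def make_fixture(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a small ready-to-run cohort with ground truth and gene sets.

    Six cell types across four samples (~800 real cells plus ambient
    barcodes, 1500 genes), synthetic marker/cell-cycle/subtype gene sets
    aligned to the synthetic gene names, the transcribed reference subtype
    score tables, and a pipeline config.  Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    types = ("epithelial", "tcell", "bcell", "myeloid", "fibroblast", "stromal")
    cell_types = syn.default_cell_types(1500, names=types)
    samples = syn.preset_samples(
        [
            ("HGA-P", "HGA", "primary", "HGSOC", 200),
            ("HGA-M", "HGA", "metastatic", "HGSOC", 200),
            ("LGA-P", "LGA", "primary", "LGSOC", 200),
            ("NRM-N", "NRM", "normal", "normal", 200),
        ],
        list(types),
    )
    config = syn.CohortConfig(
        n_genes=1500,
        cell_types=cell_types,
        samples=samples,
        ambient_barcodes=(400, 20.0),
        seed=seed,
    )
    counts, meta, truth = syn.generate_cohort(config)

    paths = {
        "matrix": out / "matrix.mtx",
        "genes": out / "genes.txt",
        "barcodes": out / "barcodes.txt",
        "meta": out / "meta.tsv",
        "truth": out / "truth.tsv",
        "cell_types": out / "true_cell_types.tsv",
        "markers": out / "markers.gmt",
        "cell_cycle": out / "cell_cycle.gmt",
        "subtypes": out / "subtypes.gmt",
        "reference_scores": out / "reference_subtype_scores.tsv",
        "config": out / "config.yaml",
    }
    write_counts(counts, paths["matrix"], paths["genes"], paths["barcodes"])
    write_cell_meta(meta, paths["meta"])
    syn.write_truth(truth, paths["truth"])
    pd.DataFrame(
        {"barcode": [m.barcode for m in meta], "cell_type": truth.cell_types}
    ).to_csv(paths["cell_types"], sep="\t", index=False)

    gene_names = counts.genes
    marker_sets = [
        GeneSet(ct.name, [gene_names[i] for i in ct.marker_genes]) for ct in cell_types
    ]
    write_gene_sets(marker_sets, paths["markers"])
    write_gene_sets(
        [
            GeneSet("S", [gene_names[i] for i in range(1000, 1043)]),
            GeneSet("G2M", [gene_names[i] for i in range(1100, 1154)]),
        ],
        paths["cell_cycle"],
    )
    blocks = {ct.name: ct.marker_genes for ct in cell_types}
    write_gene_sets(
        [
            GeneSet("differentiated", [gene_names[i] for i in blocks["epithelial"]]),
            GeneSet(
                "immunoreactive",
                [gene_names[i] for i in blocks["tcell"] + blocks["bcell"] + blocks["myeloid"]],
            ),
            GeneSet(
                "mesenchymal",
                [gene_names[i] for i in blocks["fibroblast"] + blocks["stromal"]],
            ),
            GeneSet("proliferative", [gene_names[i] for i in range(1200, 1225)]),
        ],
        paths["subtypes"],
    )
    from importlib import resources

    src = resources.files("serocell.data").joinpath("subtype_scores.tsv")
    paths["reference_scores"].write_text(src.read_text())

    run_config = {
        "seed": seed,
        "inputs": {
            "matrix": "matrix.mtx",
            "genes": "genes.txt",
            "barcodes": "barcodes.txt",
            "meta": "meta.tsv",
        },
        "gene_sets": {
            "markers": "markers.gmt",
            "cell_cycle": "cell_cycle.gmt",
            "subtypes": "subtypes.gmt",
        },
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(run_config, fh, sort_keys=False)
    return paths
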