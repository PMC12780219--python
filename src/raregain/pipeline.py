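"""End-to-end orchestration of the rare-cell detection workflow.

simulate/ingest -> QC -> log-normalize -> CNV gate (on diploid-referenced
smoothed expression) -> input-gain PCA clustering of CNV-positive cells ->
marker-cluster identification -> recovery metrics -> differential expression
(marker cluster vs remaining CNV-positive cells) -> gene-set enrichment and
overlap. Every stochastic stage receives a seed derived from the single
pipeline seed plus the stage index, so stages are isolated but jointly
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from . import cnv, dge, gain, gsea, qc, simulate
from .io import CountMatrix, GeneTable, NormalizedMatrix

__all__ = ["PipelineConfig", "RunManifest", "run_full", "ingest_external"]

_DEFAULTS: dict[str, object] = {
    "qc.min_genes": 200,
    "qc.max_mito": 0.05,
    "norm.scale_factor": 1e4,
    "hvg.n_top": 2000,
    "scale.clip": 10.0,
    "gain.markers": list(simulate.DEFAULT_MARKERS),
    "gain.gain": 5.0,
    "gain.force_hvg": True,
    "cluster.n_pcs": 30,
    "cluster.k_neighbors": 15,
    "cluster.resolution": 1.0,
    "cnv.window": 101,
    "cnv.clamp": 3.0,
    "cnv.threshold": 1.009,
    "cnv.level": "cell",
    "dge.method": "wilcoxon",
    "dge.alpha": 0.05,
    "gsea.weight": 1.0,
    "gsea.n_perm": 1000,
    "seed": 0,
}


@dataclass
class PipelineConfig:
    """Flat dotted-key parameter map covering every stage; unknown keys rejected."""

    params: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.params) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(_DEFAULTS)
        merged.update(self.params)
        self.params = merged

    def __getitem__(self, key: str):
        return self.params[key]

    @property
    def seed(self) -> int:
        return int(self.params["seed"])

    def stage_seed(self, stage_index: int) -> int:
        return (self.seed + stage_index) % (2**31 - 1)

    def hash(self) -> str:
        payload = json.dumps(self.params, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    stages: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def record(self, name: str, t0: float, **info) -> None:
        self.stages.append(
            {"stage": name, "wall_time_s": round(time.perf_counter() - t0, 3), **info}
        )

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"config_hash": self.config_hash, "stages": self.stages,
             "summary": self.summary},
            indent=2,
            default=_jsonable,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_full(
    config: PipelineConfig,
    counts: CountMatrix,
    gene_table: GeneTable,
    reference_cells: set[str],
    truth_labels: dict[str, str] | None = None,
    gene_sets: dict[str, list[str]] | None = None,
    out_dir=None,
) -> RunManifest:
    """Execute the full workflow on a count matrix.

    ``reference_cells`` are the presumed-diploid cells anchoring the CNV
    baseline (the synthetic truth label, or an annotation-derived barcode
    list for ingested data). ``truth_labels`` (barcode -> label) are optional
    and only add planted-population recall/precision to the summary.
    """
    cfg = config
    manifest = RunManifest(config_hash=cfg.hash())
    markers = list(cfg["gain.markers"])

    t0 = time.perf_counter()
    filtered = qc.filter_cells(
        counts, gene_table, min_genes=int(cfg["qc.min_genes"]),
        max_mito=float(cfg["qc.max_mito"]),
    )
    manifest.record("qc_filter", t0, cells_in=counts.n_cells,
                    cells_out=filtered.n_cells)

    t0 = time.perf_counter()
    norm = qc.lognormalize(filtered, scale_factor=float(cfg["norm.scale_factor"]))
    manifest.record("lognormalize", t0, cells=norm.n_cells, genes=norm.n_genes)

    t0 = time.perf_counter()
    ref_present = reference_cells & set(norm.cell_ids)
    cnv_res = cnv.smooth_relative_expression(
        norm, gene_table, ref_present,
        window=int(cfg["cnv.window"]), clamp=float(cfg["cnv.clamp"]),
    )
    scores = cnv.cnv_score(cnv_res.modified_expression)
    cnv_pos = cnv.select_cnv_positive(
        scores, threshold=float(cfg["cnv.threshold"]), level=str(cfg["cnv.level"])
    )
    # reference cells anchor the baseline and are never treated as tumor
    cnv_pos &= ~np.isin(norm.cell_ids, list(ref_present))
    manifest.record("cnv_gate", t0, cnv_positive=int(cnv_pos.sum()),
                    reference=len(ref_present))

    t0 = time.perf_counter()
    tumor_counts = filtered.subset_cells(cnv_pos)
    tumor_norm = qc.lognormalize(
        tumor_counts, scale_factor=float(cfg["norm.scale_factor"])
    )
    spec = gain.GainSpec(
        marker_genes=markers, gain=float(cfg["gain.gain"]),
        force_hvg=bool(cfg["gain.force_hvg"]),
    )
    gained = gain.apply_input_gain(tumor_norm, spec)
    qc.select_hvg(gained, n_top=min(int(cfg["hvg.n_top"]), gained.n_genes))
    scaled = qc.scale_features(gained, clip=float(cfg["scale.clip"]))
    embedding = gain.pca_embed(
        scaled, n_pcs=min(int(cfg["cluster.n_pcs"]), min(scaled.shape) - 1),
        seed=cfg.stage_seed(1),
    )
    labels = gain.build_graph_and_cluster(
        embedding, k_neighbors=int(cfg["cluster.k_neighbors"]),
        resolution=float(cfg["cluster.resolution"]), seed=cfg.stage_seed(2),
    )
    marker_cluster = gain.identify_marker_cluster(labels, tumor_norm, markers)
    manifest.record("gain_clustering", t0, cells=tumor_norm.n_cells,
                    n_clusters=int(labels.max() + 1) if len(labels) else 0,
                    marker_cluster=marker_cluster)

    t0 = time.perf_counter()
    threshold_cells = gain.marker_threshold_select(tumor_norm, markers)
    if marker_cluster is not None:
        cluster_cells = {
            tumor_norm.cell_ids[i]
            for i in np.flatnonzero(labels == marker_cluster)
        }
    else:
        cluster_cells = set()
    metrics = gain.recovery_metrics(
        cluster_cells, threshold_cells, total_cells=norm.n_cells
    )
    manifest.record("recovery", t0, threshold_cells=len(threshold_cells),
                    cluster_size=metrics.cluster_size)

    summary: dict[str, object] = {
        "cells_ingested": counts.n_cells,
        "cells_after_qc": filtered.n_cells,
        "cnv_positive_cells": int(cnv_pos.sum()),
        "marker_cluster_id": marker_cluster,
        "marker_cluster_size": metrics.cluster_size,
        "threshold_cells": len(threshold_cells),
        "recovery_fraction": metrics.recovery_fraction,
        "threshold_precision": metrics.precision,
        "population_fraction": metrics.cluster_size / max(norm.n_cells, 1),
    }

    if truth_labels is not None:
        srcc = {
            c for c, lab in truth_labels.items() if lab == simulate.LABEL_SRCC
        }
        tp = len(cluster_cells & srcc)
        summary["planted_srcc"] = len(srcc)
        summary["planted_recall"] = tp / len(srcc) if srcc else None
        summary["planted_precision"] = (
            tp / len(cluster_cells) if cluster_cells else None
        )

    # DGE: marker cluster vs remaining CNV-positive (non-cluster) cells
    dge_table = None
    if marker_cluster is not None and metrics.cluster_size >= 3:
        t0 = time.perf_counter()
        non_cluster = [c for c in tumor_norm.cell_ids if c not in cluster_cells]
        dge_table = dge.differential_expression(
            tumor_norm, tumor_counts, sorted(cluster_cells), non_cluster,
            method=str(cfg["dge.method"]),
        )
        alpha = float(cfg["dge.alpha"])
        n_deg = int((dge_table["adj_p"] < alpha).sum())
        summary["n_deg"] = n_deg
        summary["n_non_cluster_comparator"] = len(non_cluster)
        manifest.record("dge", t0, n_deg=n_deg)

        if gene_sets:
            t0 = time.perf_counter()
            ranked = ranked_statistic(dge_table)
            gsea_res = gsea.gsea_table(
                ranked, gene_sets, weight=float(cfg["gsea.weight"]),
                n_perm=int(cfg["gsea.n_perm"]), seed=cfg.stage_seed(3),
            )
            summary["enriched_sets"] = {
                name: {"nes": row["nes"], "p_perm": row["p_perm"],
                       "adj_p": row["adj_p"]}
                for name, row in gsea_res.iterrows()
            }
            manifest.record("gsea", t0, n_sets=len(gsea_res))
            if out_dir is not None:
                gsea_res.to_csv(Path(out_dir) / "gsea.tsv", sep="\t")

    manifest.summary = summary
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        lab_df = pd.DataFrame(
            {
                "barcode": tumor_norm.cell_ids,
                "cluster": labels,
                "is_marker_cluster": (
                    labels == marker_cluster if marker_cluster is not None
                    else np.zeros(len(labels), dtype=bool)
                ).astype(int),
            }
        )
        lab_df.to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
        if dge_table is not None:
            dge_table.to_csv(out_dir / "dge.tsv", sep="\t")
        manifest.to_json(out_dir / "manifest.json")
    return manifest


def gain_sweep(
    config: PipelineConfig,
    counts: CountMatrix,
    gene_table: GeneTable,
    reference_cells: set[str],
    gains: list[float],
    truth_labels: dict[str, str] | None = None,
) -> dict[float, dict]:
    """Clustering metrics for several input gains on one dataset.

    QC, normalization and the CNV gate do not depend on the gain, so they
    are computed once; the gain -> HVG -> scale -> PCA -> Leiden ->
    identification chain is re-run per gain with the same stage seeds.
    Returns a mapping gain -> summary (same keys as the clustering part of
    :func:`run_full`).
    """
    cfg = config
    markers = list(cfg["gain.markers"])
    filtered = qc.filter_cells(
        counts, gene_table, min_genes=int(cfg["qc.min_genes"]),
        max_mito=float(cfg["qc.max_mito"]),
    )
    norm = qc.lognormalize(filtered, scale_factor=float(cfg["norm.scale_factor"]))
    ref_present = reference_cells & set(norm.cell_ids)
    cnv_res = cnv.smooth_relative_expression(
        norm, gene_table, ref_present,
        window=int(cfg["cnv.window"]), clamp=float(cfg["cnv.clamp"]),
    )
    scores = cnv.cnv_score(cnv_res.modified_expression)
    cnv_pos = cnv.select_cnv_positive(
        scores, threshold=float(cfg["cnv.threshold"]), level=str(cfg["cnv.level"])
    )
    cnv_pos &= ~np.isin(norm.cell_ids, list(ref_present))
    tumor_counts = filtered.subset_cells(cnv_pos)
    tumor_norm = qc.lognormalize(
        tumor_counts, scale_factor=float(cfg["norm.scale_factor"])
    )
    threshold_cells = gain.marker_threshold_select(tumor_norm, markers)
    srcc = (
        {c for c, lab in truth_labels.items() if lab == simulate.LABEL_SRCC}
        if truth_labels is not None
        else None
    )

    out: dict[float, dict] = {}
    for g in gains:
        spec = gain.GainSpec(
            marker_genes=markers, gain=float(g),
            force_hvg=bool(cfg["gain.force_hvg"]),
        )
        gained = gain.apply_input_gain(tumor_norm, spec)
        qc.select_hvg(gained, n_top=min(int(cfg["hvg.n_top"]), gained.n_genes))
        scaled = qc.scale_features(gained, clip=float(cfg["scale.clip"]))
        embedding = gain.pca_embed(
            scaled, n_pcs=min(int(cfg["cluster.n_pcs"]), min(scaled.shape) - 1),
            seed=cfg.stage_seed(1),
        )
        labels = gain.build_graph_and_cluster(
            embedding, k_neighbors=int(cfg["cluster.k_neighbors"]),
            resolution=float(cfg["cluster.resolution"]), seed=cfg.stage_seed(2),
        )
        marker_cluster = gain.identify_marker_cluster(labels, tumor_norm, markers)
        cluster_cells = (
            {tumor_norm.cell_ids[i] for i in np.flatnonzero(labels == marker_cluster)}
            if marker_cluster is not None
            else set()
        )
        metrics = gain.recovery_metrics(
            cluster_cells, threshold_cells, total_cells=norm.n_cells
        )
        summary = {
            "marker_cluster_id": marker_cluster,
            "marker_cluster_size": metrics.cluster_size,
            "threshold_cells": len(threshold_cells),
            "recovery_fraction": metrics.recovery_fraction,
            "threshold_precision": metrics.precision,
            "population_fraction": metrics.population_fraction,
            "cnv_positive_cells": tumor_norm.n_cells,
        }
        if srcc is not None:
            tp = len(cluster_cells & srcc)
            summary["planted_srcc"] = len(srcc)
            summary["planted_recall"] = tp / len(srcc) if srcc else None
            summary["planted_precision"] = (
                tp / len(cluster_cells) if cluster_cells else None
            )
        out[float(g)] = summary
    return out


def ranked_statistic(dge_table: pd.DataFrame, kind: str = "signed_logp") -> pd.Series:
    """Per-gene ranking statistic for preranked GSEA.

    ``signed_logp`` (default): sign(log2fc) * -log10(p), p floored at 1e-300;
    ``log2fc``: the fold change itself.
    """
    if kind == "log2fc":
        return dge_table["log2fc"]
    if kind != "signed_logp":
        raise ValueError("kind must be 'signed_logp' or 'log2fc'")
    p = np.maximum(dge_table["p_value"].to_numpy(dtype=float), 1e-300)
    return pd.Series(
        np.sign(dge_table["log2fc"].to_numpy()) * -np.log10(p),
        index=dge_table.index,
    )


def ingest_external(
    matrix_path, barcodes_path, genes_path, annotations_path=None,
    reference_annotations: tuple[str, ...] = ("Fibroblasts", "B lymphocytes"),
) -> tuple[CountMatrix, GeneTable, set[str]]:
    """Normalize an external MTX-triplet (or dense TSV) export into the
    internal model.

    The matrix may be cells x genes or genes x cells; orientation is resolved
    against the sidecar lengths. An optional annotation TSV
    (barcode<TAB>cell_type) marks the CNV reference set: barcodes whose
    annotation matches ``reference_annotations`` (case-insensitive).
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        mat = sp.csr_matrix(scipy.io.mmread(matrix_path))
    else:
        mat = sp.csr_matrix(
            pd.read_csv(matrix_path, sep="\t", header=None).to_numpy()
        )
    barcodes = (
        pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    )
    if len(barcodes) != len(set(barcodes)):
        raise ValueError("duplicated barcodes in input")
    genes_df = pd.read_csv(genes_path, sep="\t", header=None)
    n_genes = len(genes_df)
    if mat.shape == (n_genes, len(barcodes)) and mat.shape[0] != mat.shape[1]:
        mat = mat.T.tocsr()
    if mat.shape != (len(barcodes), n_genes):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(barcodes)} barcodes "
            f"x {n_genes} genes"
        )

    if genes_df.shape[1] >= 4:
        genes_df = genes_df.iloc[:, :4]
        genes_df.columns = ["gene_id", "chromosome", "start", "mito"]
        table = GeneTable(
            genes_df.assign(
                gene_id=genes_df["gene_id"].astype(str),
                mito=genes_df["mito"].astype(int).astype(bool),
            )
        )
    else:
        # positions unavailable: CNV stage cannot run on this table
        ids = genes_df.iloc[:, 0].astype(str)
        table = GeneTable(
            pd.DataFrame(
                {
                    "gene_id": ids,
                    "chromosome": "unknown",
                    "start": np.arange(1, n_genes + 1),
                    "mito": ids.str.upper().str.startswith("MT-"),
                }
            )
        )
        import warnings as _w

        _w.warn("gene positions missing; CNV scoring will be unreliable")

    counts = CountMatrix(mat.astype(np.int64), barcodes, table.gene_ids)
    reference: set[str] = set()
    if annotations_path is not None:
        ann = pd.read_csv(
            annotations_path, sep="\t", header=None, names=["barcode", "cell_type"]
        )
        wanted = {a.lower() for a in reference_annotations}
        reference = set(
            ann.loc[ann["cell_type"].str.lower().isin(wanted), "barcode"].astype(str)
        )
    return counts, table, reference
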