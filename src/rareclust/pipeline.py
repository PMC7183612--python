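"""End-to-end orchestration: load -> filter -> normalize -> dual clustering
-> weighted consensus -> rare-cluster flags."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import platform
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import consensus as cons
from . import fano_select, gini_select, graph_cluster, io_preprocess
from .graph_cluster import Partition
from .io_preprocess import CountMatrix

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_on_matrix",
           "stage_seed"]

logger = logging.getLogger("rareclust")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) from the single run seed."""
    digest = hashlib.blake2s(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunConfig:
    """Every tunable of the pipeline, serialized verbatim into the run log."""

    input_path: str | None = None
    input_format: str = "10x_mtx"  # or "csv"
    exclude_barcodes: str | None = None  # optional file, one barcode per line
    min_cells_per_gene: int = 10
    min_genes_per_cell: int = 500
    target_sum: float = 1e4
    gini_threshold: float = 0.6
    gini_p_threshold: float = 1e-4
    loess_span: float = 0.9
    loess_outlier_p: float = 0.05
    neighbors_gini: int = 5  # 15 was used for the million-cell run
    neighbors_fano: int = 15
    method: str = "leiden"  # or "louvain"
    resolution_gini: float = 1.0
    resolution_fano: float = 1.0
    hvg_method: str = "top_n"
    n_top_genes: int = 2000
    n_pcs: int = 50
    weight_mu: float = 0.1
    weight_s: float = 0.05
    weight_f: float = 1.0
    k_consensus: int | None = None  # default: max of branch cluster counts
    rare_threshold: float = 0.01
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class PipelineResult:
    config: RunConfig
    matrix: CountMatrix  # filtered raw counts
    normalized: CountMatrix
    gini_table: pd.DataFrame
    gini_genes: list[str]
    gini_partition: Partition
    fano_table: pd.DataFrame
    hvg_genes: list[str]
    embedding: np.ndarray
    fano_partition: Partition
    rep_set: cons.RepresentativeSet
    consensus_mbar: np.ndarray
    final: Partition
    rare_flags: np.ndarray
    summary: dict = field(default_factory=dict)

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.matrix.cell_ids,
                "gini_label": self.gini_partition.labels,
                "fano_label": self.fano_partition.labels,
                "consensus_label": self.final.labels,
                "is_rare": self.rare_flags[self.final.labels],
            }
        )


def _gene_subset(m: CountMatrix, genes: list[str]) -> CountMatrix:
    pos = {g: j for j, g in enumerate(m.gene_ids)}
    idx = [pos[g] for g in genes]
    return CountMatrix(
        m.values[:, idx], m.cell_ids, genes, normalized=m.normalized
    )


def run_on_matrix(m_raw: CountMatrix, config: RunConfig) -> PipelineResult:
    """Run the full pipeline on an in-memory raw count matrix."""
    cfg = config
    try:
        filtered = io_preprocess.filter_matrix(
            m_raw, cfg.min_cells_per_gene, cfg.min_genes_per_cell
        )
        norm = io_preprocess.normalize_per_cell(filtered, cfg.target_sum)
    except ValueError as e:
        raise RuntimeError(
            f"[preprocess] {e}; loosen the filter thresholds or check the "
            "input matrix"
        ) from e
    logger.info("filtered to %d cells x %d genes", norm.n_cells, norm.n_genes)

    # --- Gini branch: high-Gini features, kNN on log1p expression ---
    try:
        gtab = gini_select.gene_gini_stats(norm)
        gtab = gini_select.loess_normalize_gini(
            gtab, span=cfg.loess_span, outlier_p=cfg.loess_outlier_p
        )
        gini_genes = gini_select.select_high_gini(
            gtab, cfg.gini_threshold, cfg.gini_p_threshold
        )
    except ValueError as e:
        raise RuntimeError(f"[gini-selection] {e}") from e
    if not gini_genes:
        raise RuntimeError(
            "[gini-selection] no high-Gini gene passed the thresholds; "
            "lower gini_threshold / raise gini_p_threshold, or the data may "
            "hold no rare population"
        )
    logger.info("%d high-Gini genes selected", len(gini_genes))
    gini_feats = np.log1p(_gene_subset(norm, gini_genes).dense())
    try:
        ggraph = graph_cluster.build_knn_graph(gini_feats, cfg.neighbors_gini)
    except ValueError as e:
        raise RuntimeError(f"[gini-graph] {e}") from e
    gini_part = graph_cluster.community_cluster(
        ggraph, cfg.method, cfg.resolution_gini,
        seed=stage_seed(cfg.seed, "gini-cluster"),
    )

    # --- Fano branch: HVGs, PCA, kNN on the embedding ---
    ftab = fano_select.fano_stats(norm)
    hvg = fano_select.select_hvg(ftab, cfg.hvg_method, cfg.n_top_genes)
    n_pcs = min(cfg.n_pcs, norm.n_cells - 1, len(hvg) - 1)
    emb = fano_select.pca_embed(
        _gene_subset(norm, hvg), n_components=n_pcs,
        seed=stage_seed(cfg.seed, "pca"),
    )
    try:
        fgraph = graph_cluster.build_knn_graph(emb, cfg.neighbors_fano)
    except ValueError as e:
        raise RuntimeError(f"[fano-graph] {e}") from e
    fano_part = graph_cluster.community_cluster(
        fgraph, cfg.method, cfg.resolution_fano,
        seed=stage_seed(cfg.seed, "fano-cluster"),
    )
    logger.info(
        "branch clusters: %d (gini), %d (fano)",
        gini_part.n_clusters, fano_part.n_clusters,
    )

    # --- weighted consensus on representatives ---
    params = cons.WeightParams(cfg.weight_mu, cfg.weight_s, cfg.weight_f)
    final, rare, rep_set, mbar = cons.consensus_cluster(
        gini_part, fano_part, params,
        k=cfg.k_consensus, rare_threshold=cfg.rare_threshold,
        seed=stage_seed(cfg.seed, "kmeans"),
    )

    summary = {
        "n_cells": norm.n_cells,
        "n_genes": norm.n_genes,
        "n_gini_genes": len(gini_genes),
        "n_hvg": len(hvg),
        "n_gini_clusters": gini_part.n_clusters,
        "n_fano_clusters": fano_part.n_clusters,
        "n_representatives": rep_set.n,
        "n_consensus_clusters": final.n_clusters,
        "n_rare_clusters": int(rare.sum()),
        "cluster_sizes": final.sizes.tolist(),
        "rare_cluster_sizes": final.sizes[rare].tolist(),
        "seed": cfg.seed,
    }
    return PipelineResult(
        cfg, filtered, norm, gtab, gini_genes, gini_part, ftab, hvg, emb,
        fano_part, rep_set, mbar, final, rare, summary,
    )


def _load_input(config: RunConfig) -> CountMatrix:
    if config.input_path is None:
        raise ValueError("config.input_path is not set")
    m = io_preprocess.load_counts(config.input_path, config.input_format)
    if config.exclude_barcodes:
        with open(config.exclude_barcodes) as fh:
            drop = {line.strip() for line in fh if line.strip()}
        keep = [i for i, c in enumerate(m.cell_ids) if c not in drop]
        m = CountMatrix(
            m.values[keep], [m.cell_ids[i] for i in keep], m.gene_ids,
            gene_symbols=m.gene_symbols,
        )
    return m


def write_outputs(result: PipelineResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    cfg = result.config
    cfg.to_yaml(os.path.join(outdir, "config.yaml"))
    result.labels_frame().to_csv(
        os.path.join(outdir, "labels.csv"), index=False
    )
    gini_select.write_gini_table(
        result.gini_table, os.path.join(outdir, "gini_genes.tsv")
    )
    fano_select.write_hvg_table(
        result.fano_table, os.path.join(outdir, "hvg.tsv")
    )
    np.savetxt(
        os.path.join(outdir, "consensus_matrix.csv"),
        result.consensus_mbar, delimiter=",",
    )
    versions = {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump({**result.summary, "versions": versions}, fh, indent=2)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Load the configured input, run everything, write the output bundle."""
    m = _load_input(config)
    result = run_on_matrix(m, config)
    if config.outdir:
        write_outputs(result, config.outdir)
    return result
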