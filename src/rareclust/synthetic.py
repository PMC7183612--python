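"""Seeded synthetic UMI count matrices with planted common and rare clusters.

Counts are negative-binomial per gene (lognormal baseline means,
log-uniform overdispersion), and each cluster receives a block of
exclusive marker genes whose mean is multiplied by a fold factor inside
that cluster only.  Markers of a rare cluster are therefore high-Gini
genes; markers of common clusters are high-Fano genes — exactly the two
signals the pipeline's branches look for.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .graph_cluster import Partition
from .io_preprocess import CountMatrix, write_counts

__all__ = ["SyntheticDesign", "SyntheticData", "generate", "standard_design"]


@dataclass(frozen=True)
class SyntheticDesign:
    """Design of a planted-cluster UMI count matrix.

    Defaults describe the standard fixture used throughout the test suite:
    2000 cells, three common clusters of ~33% and one rare cluster of ~1%,
    each with 20 exclusive markers upregulated 20-fold over a
    negative-binomial baseline.  The rare proportion is set to 0.0095
    (19 of 2000 cells) rather than 0.0100: the rare-cluster rule is the
    strict inequality ``proportion < 0.01``, so a planted population at
    exactly 1% could never be flagged even when recovered perfectly.
    """

    n_cells: int = 2000
    n_genes: int = 3000
    cluster_proportions: tuple[float, ...] = (0.33, 0.33, 0.3305, 0.0095)
    rare_indices: tuple[int, ...] = (3,)
    markers_per_cluster: int = 20
    marker_fold: float = 20.0
    base_mean_log_mu: float = float(np.log(0.5))
    base_mean_log_sigma: float = 1.0
    dispersion_range: tuple[float, float] = (0.1, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.cluster_proportions, dtype=float)
        if abs(props.sum() - 1.0) > 1e-8:
            raise ValueError("cluster proportions must sum to 1")
        if (props.min() * self.n_cells) < 5:
            raise ValueError("smallest cluster would have fewer than 5 cells")
        if self.markers_per_cluster * len(props) > self.n_genes:
            raise ValueError("not enough genes for the requested markers")
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must exceed 1")


@dataclass(frozen=True)
class SyntheticData:
    counts: CountMatrix
    labels: Partition  # ground truth, size-ordered
    markers: dict[int, list[str]] = field(repr=False)  # true label -> genes

    def __iter__(self):  # allows: counts, labels = generate(design)
        return iter((self.counts, self.labels))


def _cluster_sizes(n_cells: int, props: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment so sizes sum exactly to n_cells."""
    raw = props * n_cells
    sizes = np.floor(raw).astype(int)
    remainder = n_cells - sizes.sum()
    order = np.argsort(-(raw - sizes), kind="stable")
    sizes[order[:remainder]] += 1
    return sizes


def generate(design: SyntheticDesign) -> SyntheticData:
    """Draw a seeded count matrix with the planted cluster structure.

    Deterministic given ``design.seed``: the same design yields a
    byte-identical matrix.  Cell order is shuffled so cluster membership is
    not encoded in row order.
    """
    rng = np.random.default_rng(design.seed)
    props = np.asarray(design.cluster_proportions, dtype=float)
    n_clusters = len(props)
    sizes = _cluster_sizes(design.n_cells, props)

    base_mean = rng.lognormal(
        design.base_mean_log_mu, design.base_mean_log_sigma, design.n_genes
    )
    lo, hi = design.dispersion_range
    dispersion = np.exp(
        rng.uniform(np.log(lo), np.log(hi), design.n_genes)
    )
    marker_idx = rng.choice(
        design.n_genes,
        size=design.markers_per_cluster * n_clusters,
        replace=False,
    ).reshape(n_clusters, design.markers_per_cluster)

    gene_ids = [f"gene{j:05d}" for j in range(design.n_genes)]
    blocks, label_blocks = [], []
    for c in range(n_clusters):
        mean_c = base_mean.copy()
        mean_c[marker_idx[c]] *= design.marker_fold
        r = 1.0 / dispersion  # NB size; variance = m + dispersion * m^2
        p = r / (r + mean_c)
        blocks.append(
            rng.negative_binomial(r, p, size=(sizes[c], design.n_genes))
        )
        label_blocks.append(np.full(sizes[c], c))
    counts = np.concatenate(blocks, axis=0)
    labels = np.concatenate(label_blocks)
    perm = rng.permutation(design.n_cells)
    counts, labels = counts[perm], labels[perm]

    m = CountMatrix(
        sp.csr_matrix(counts),
        [f"cell{i:05d}" for i in range(design.n_cells)],
        gene_ids,
    )
    part = Partition.from_labels(labels)
    # map planted cluster ids to their size-ordered Partition labels
    relabel = {}
    for planted, final in zip(labels, part.labels):
        relabel.setdefault(int(planted), int(final))
    markers = {
        relabel[c]: [gene_ids[j] for j in marker_idx[c]]
        for c in range(n_clusters)
    }
    return SyntheticData(m, part, markers)


def standard_design(seed: int = 0) -> SyntheticDesign:
    """The default fixture design with only the seed varied."""
    return SyntheticDesign(seed=seed)


def write_fixture(data: SyntheticData, outdir: str) -> None:
    """Write the fixture as a 10x MTX triplet, a CSV, and true labels."""
    os.makedirs(outdir, exist_ok=True)
    write_counts(data.counts, os.path.join(outdir, "mtx"), format="10x_mtx")
    write_counts(data.counts, os.path.join(outdir, "counts.csv"), format="csv")
    pd.DataFrame(
        {"cell_id": data.counts.cell_ids, "true_label": data.labels.labels}
    ).to_csv(os.path.join(outdir, "true_labels.csv"), index=False)
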