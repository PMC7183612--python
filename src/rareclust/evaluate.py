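"""Partition-agreement metrics and the rare-preserving robustness protocol.

The robustness check mirrors how the method is stress-tested in practice:
keep every cell of the rare clusters (they are the point of the exercise),
subsample the common clusters to 50%, rerun the whole pipeline — feature
selection included — and compare the new labels to the baseline with NMI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import normalized_mutual_info_score

from .graph_cluster import Partition
from .io_preprocess import CountMatrix
from .pipeline import RunConfig, run_on_matrix

__all__ = ["nmi", "SubsampleScheme", "RobustnessResult", "robustness_protocol"]

logger = logging.getLogger("rareclust")


def nmi(a, b, average_method: str = "arithmetic") -> float:
    """Normalized mutual information between two partitions of one cell set.

    Normalized by the arithmetic mean of the entropies by default
    (``geometric`` is accepted for the alternative convention).  A
    zero-entropy partition (everything in one cluster) yields 0 against any
    non-identical partition.
    """
    la = a.labels if isinstance(a, Partition) else np.asarray(a)
    lb = b.labels if isinstance(b, Partition) else np.asarray(b)
    if la.size != lb.size:
        raise ValueError(f"partitions cover {la.size} vs {lb.size} cells")
    return float(
        normalized_mutual_info_score(la, lb, average_method=average_method)
    )


@dataclass(frozen=True)
class SubsampleScheme:
    """Rare-preserving subsampling: keep rare clusters whole, draw a
    fraction of each common cluster (stratified), repeat."""

    common_fraction: float = 0.5
    rare_threshold: float = 0.01
    n_repeats: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.common_fraction <= 1:
            raise ValueError("common_fraction must lie in (0, 1]")


@dataclass
class RobustnessResult:
    nmi_values: list[float]
    median: float
    table: pd.DataFrame  # repeat, retained_cells, n_clusters, nmi


def _retained_indices(
    baseline: Partition, scheme: SubsampleScheme, rng: np.random.Generator
) -> np.ndarray:
    rare_labels = np.flatnonzero(baseline.proportions < scheme.rare_threshold)
    keep = [np.flatnonzero(np.isin(baseline.labels, rare_labels))]
    common_labels = np.flatnonzero(
        baseline.proportions >= scheme.rare_threshold
    )
    if scheme.stratified:
        for lab in common_labels:
            members = np.flatnonzero(baseline.labels == lab)
            n_draw = int(np.floor(scheme.common_fraction * members.size))
            keep.append(rng.choice(members, size=n_draw, replace=False))
    else:
        members = np.flatnonzero(np.isin(baseline.labels, common_labels))
        n_draw = int(np.floor(scheme.common_fraction * members.size))
        keep.append(rng.choice(members, size=n_draw, replace=False))
    return np.sort(np.concatenate(keep))


def robustness_protocol(
    m: CountMatrix,
    baseline: Partition,
    scheme: SubsampleScheme,
    config: RunConfig,
) -> RobustnessResult:
    """Rerun the pipeline on rare-preserving subsamples and score stability.

    ``m`` is the raw (unnormalized) matrix on which ``baseline`` was
    computed with ``config``; each repeat reruns the complete pipeline on
    the retained cells and reports NMI against the baseline restricted to
    the cells present in the rerun result (the rerun's own filtering may
    drop a few more).
    """
    if baseline.n_cells != m.n_cells:
        raise ValueError("baseline must cover every cell of the matrix")
    rows = []
    values: list[float] = []
    for rep in range(scheme.n_repeats):
        rng = np.random.default_rng((scheme.seed + 9973 * rep) % 2**31)
        idx = _retained_indices(baseline, scheme, rng)
        sub = CountMatrix(
            m.values[idx],
            [m.cell_ids[i] for i in idx],
            m.gene_ids,
            normalized=False,
        )
        result = run_on_matrix(sub, config)
        pos = {c: i for i, c in enumerate(m.cell_ids)}
        base_idx = np.array([pos[c] for c in result.matrix.cell_ids])
        value = nmi(baseline.labels[base_idx], result.final.labels)
        if result.final.n_clusters == 1:
            logger.warning("repeat %d collapsed to a single cluster", rep)
        values.append(value)
        rows.append(
            {
                "repeat": rep,
                "retained_cells": idx.size,
                "n_clusters": result.final.n_clusters,
                "nmi": value,
            }
        )
    table = pd.DataFrame(rows)
    return RobustnessResult(values, float(np.median(values)), table)
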