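"""Cluster-aware weighted consensus of the Gini and Fano partitions.

Cells sharing the same (Gini-label, Fano-label) pair are collapsed onto one
representative, so the consensus cost scales with the number of occupied
label pairs n, not the number of cells N.  For representatives i, j the
agreement matrix is

    Mbar_ij = wG_ij * M_ij(P_G) + wF_ij * M_ij(P_F)

where M(P) is the binary co-membership (connectivity) matrix of partition P
and the weights derive from a logistic function of Gini-cluster size: a
cell in a tiny Gini cluster trusts the Gini branch, a cell in a huge one
trusts the Fano branch.  k-means on the rows of Mbar yields the consensus
labels, which are expanded back to cells; clusters holding under 1% of all
cells are flagged rare.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.cluster import KMeans

from .graph_cluster import Partition

__all__ = [
    "WeightParams",
    "RepresentativeSet",
    "collapse_representatives",
    "connectivity_matrix",
    "gini_weight",
    "pair_weights",
    "consensus_matrix",
    "partition_consensus",
    "expand_and_flag",
    "consensus_cluster",
]


@dataclass(frozen=True)
class WeightParams:
    """Parameters of the logistic Gini-branch weight.

    mu: cluster proportion at which the Gini and Fano branches are trusted
    equally (the weight crosses 0.5).  s: how fast trust in the Gini branch
    decays above mu.  f_const: the constant un-normalized Fano weight.
    """

    mu: float = 0.1
    s: float = 0.05
    f_const: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.mu < 1):
            raise ValueError("mu must lie in (0, 1)")
        if self.s <= 0 or self.f_const <= 0:
            raise ValueError("s and f_const must be positive")


@dataclass(frozen=True)
class RepresentativeSet:
    """One representative cell per occupied (Gini-label, Fano-label) pair."""

    pairs: np.ndarray  # (n, 2) int, lexicographically sorted, distinct
    representative_cell: np.ndarray  # (n,) lowest cell index of each pair
    multiplicity: np.ndarray  # (n,) cells carrying each pair
    cell_to_pair: np.ndarray  # (N,) pair index of every cell

    @property
    def n(self) -> int:
        return len(self.pairs)

    @property
    def n_cells(self) -> int:
        return len(self.cell_to_pair)


def collapse_representatives(
    gini: Partition, fano: Partition
) -> RepresentativeSet:
    """Collapse cells with identical branch labels onto representatives."""
    if gini.n_cells != fano.n_cells:
        raise ValueError(
            f"partitions cover {gini.n_cells} vs {fano.n_cells} cells"
        )
    pairs = np.stack([gini.labels, fano.labels], axis=1)
    uniq, inverse, counts = np.unique(
        pairs, axis=0, return_inverse=True, return_counts=True
    )
    reps = np.full(len(uniq), gini.n_cells, dtype=int)
    np.minimum.at(reps, inverse, np.arange(gini.n_cells))
    return RepresentativeSet(uniq, reps, counts, inverse)


def connectivity_matrix(labels) -> np.ndarray:
    """Binary co-membership matrix: 1 iff two items share a cluster."""
    lab = np.asarray(labels)
    return (lab[:, None] == lab[None, :]).astype(float)


def gini_weight(x, params: WeightParams) -> float | np.ndarray:
    """Un-normalized Gini-branch weight, logistic-decreasing in cluster size.

    ``x`` is the proportion (over all cells) of the Gini cluster containing
    the cell.  Equals 0.5 at x = mu and approaches 1 as x -> 0.
    """
    arr = np.asarray(x, dtype=float)
    if (arr <= 0).any() or (arr > 1).any():
        raise ValueError("cluster proportions must lie in (0, 1]")
    w = expit(-(arr - params.mu) / params.s)  # == 1 - 1/(1+exp(-(x-mu)/s))
    return float(w) if np.isscalar(x) else w


def pair_weights(
    rep_set: RepresentativeSet,
    gini: Partition,
    params: WeightParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized pairwise branch weights (wG, wF), summing to 1 elementwise.

    Per representative, the raw Gini weight is the logistic weight of its
    cell's Gini-cluster proportion — computed over ALL cells, so collapsing
    does not distort cluster sizes.  Pairs combine by max on the Gini side
    and the constant f_const on the Fano side, then normalize.
    """
    gini_labels = rep_set.pairs[:, 0]
    x = gini.proportions[gini_labels]
    wtg = gini_weight(x, params)
    wtg_pair = np.maximum.outer(wtg, wtg)
    wg = wtg_pair / (wtg_pair + params.f_const)
    return wg, 1.0 - wg


def consensus_matrix(
    m_gini: np.ndarray,
    m_fano: np.ndarray,
    w_gini: np.ndarray,
    w_fano: np.ndarray,
) -> np.ndarray:
    """Weighted elementwise combination of the two connectivity matrices."""
    shapes = {m_gini.shape, m_fano.shape, w_gini.shape, w_fano.shape}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch among inputs: {shapes}")
    mbar = w_gini * m_gini + w_fano * m_fano
    return mbar


def partition_consensus(mbar: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-means over the rows of the consensus matrix.

    Rows of Mbar are the representatives' agreement profiles; k-means++
    with 10 restarts, seeded.  Labels are compacted (empty clusters drop
    out of the numbering).
    """
    n = mbar.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must lie in [2, {n}] for {n} representatives")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    raw = km.fit_predict(mbar)
    _, compact = np.unique(raw, return_inverse=True)
    return compact


def expand_and_flag(
    rep_labels: np.ndarray,
    rep_set: RepresentativeSet,
    rare_threshold: float = 0.01,
) -> tuple[Partition, np.ndarray]:
    """Expand representative labels back to cells and flag rare clusters.

    Every cell inherits its representative's consensus label.  A cluster is
    rare iff its proportion of ALL cells is strictly below
    ``rare_threshold`` (a cluster at exactly the threshold is common).
    Returns the size-ordered cell Partition and a boolean rare flag per
    cluster label.
    """
    rep_labels = np.asarray(rep_labels)
    if rep_labels.size != rep_set.n:
        raise ValueError("one label per representative required")
    cells = Partition.from_labels(rep_labels[rep_set.cell_to_pair])
    rare = cells.proportions < rare_threshold
    return cells, rare


def consensus_cluster(
    gini: Partition,
    fano: Partition,
    params: WeightParams | None = None,
    k: int | None = None,
    rare_threshold: float = 0.01,
    seed: int = 0,
) -> tuple[Partition, np.ndarray, RepresentativeSet, np.ndarray]:
    """Full consensus step: collapse, weight, combine, k-means, expand.

    ``k`` defaults to the larger of the two branch cluster counts,
    preserving whichever branch is finer.  Returns (cell partition, rare
    flags, representative set, consensus matrix).
    """
    params = params or WeightParams()
    rep_set = collapse_representatives(gini, fano)
    mg = connectivity_matrix(rep_set.pairs[:, 0])
    mf = connectivity_matrix(rep_set.pairs[:, 1])
    wg, wf = pair_weights(rep_set, gini, params)
    mbar = consensus_matrix(mg, mf, wg, wf)
    if k is None:
        k = max(gini.n_clusters, fano.n_clusters)
    if k < 2 or rep_set.n < 2:
        rep_labels = np.zeros(rep_set.n, dtype=int)
    else:
        rep_labels = partition_consensus(mbar, min(k, rep_set.n), seed=seed)
    cells, rare = expand_and_flag(rep_labels, rep_set, rare_threshold)
    return cells, rare, rep_set, mbar
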