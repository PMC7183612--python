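"""k-nearest-neighbor graph construction and community detection.

Both the Gini branch (log1p expression over selected high-Gini genes) and
the Fano branch (PCA embedding of highly variable genes) go through the
same machinery: a Euclidean kNN graph, symmetrized by union and weighted
by shared-neighbor (Jaccard) overlap, partitioned with Leiden or Louvain.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

__all__ = ["Partition", "build_knn_graph", "community_cluster"]


@dataclass(frozen=True)
class Partition:
    """A hard clustering of N cells: contiguous 0-based integer labels.

    Labels are ordered by decreasing cluster size (label 0 = largest; ties
    broken by first occurrence), so they are comparable across runs.
    """

    labels: np.ndarray
    n_clusters: int = field(init=False)
    sizes: np.ndarray = field(init=False)
    proportions: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        if labels.ndim != 1 or labels.size == 0:
            raise ValueError("labels must be a nonempty 1-d integer vector")
        uniq, counts = np.unique(labels, return_counts=True)
        if uniq.min() != 0 or uniq.max() != len(uniq) - 1:
            raise ValueError("labels must be contiguous and 0-based")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "n_clusters", len(uniq))
        object.__setattr__(self, "sizes", counts)
        object.__setattr__(self, "proportions", counts / labels.size)

    @classmethod
    def from_labels(cls, raw_labels, relabel_by_size: bool = True) -> "Partition":
        """Build a Partition from arbitrary hashable labels.

        With ``relabel_by_size`` clusters are renumbered by decreasing size;
        otherwise by first occurrence.
        """
        raw = np.asarray(raw_labels)
        uniq, first, inverse, counts = np.unique(
            raw, return_index=True, return_inverse=True, return_counts=True
        )
        if relabel_by_size:
            # stable sort: ties keep np.unique's (sorted-label) order
            order = np.argsort(-counts, kind="stable")
        else:
            order = np.argsort(first, kind="stable")
        remap = np.empty(len(uniq), dtype=int)
        remap[order] = np.arange(len(uniq))
        return cls(remap[inverse])

    @property
    def n_cells(self) -> int:
        return self.labels.size


def build_knn_graph(
    features: np.ndarray,
    n_neighbors: int,
    weighting: str = "jaccard",
) -> ig.Graph:
    """Undirected kNN graph over rows of ``features``.

    Each point is linked to its ``n_neighbors`` Euclidean nearest neighbors
    (self excluded); directed links are symmetrized by union.  With
    ``weighting='jaccard'`` each edge carries the Jaccard overlap of the two
    endpoints' neighbor sets (self-inclusive), emphasizing edges inside
    dense neighborhoods; ``'uniform'`` gives unit weights.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-d cells x dims array")
    n = X.shape[0]
    if n_neighbors < 1 or n_neighbors >= n:
        raise ValueError(
            f"n_neighbors must be in [1, {n - 1}] for {n} cells"
        )
    tree = cKDTree(X)
    _, idx = tree.query(X, k=n_neighbors + 1)
    idx = np.atleast_2d(idx)
    # drop self per row (with duplicated points the self column is not
    # guaranteed to be first)
    neigh = np.empty((n, n_neighbors), dtype=int)
    for i in range(n):
        row = idx[i]
        row = row[row != i][:n_neighbors]
        if row.size < n_neighbors:  # self missing from ties: take first k
            row = idx[i][idx[i] != i]
            row = np.concatenate([row, idx[i][: n_neighbors - row.size]])
        neigh[i] = row[:n_neighbors]

    rows = np.repeat(np.arange(n), n_neighbors)
    cols = neigh.ravel()
    a, b = np.minimum(rows, cols), np.maximum(rows, cols)
    edges = np.unique(np.stack([a, b], axis=1), axis=0)

    if weighting == "jaccard":
        # indicator matrix of self-inclusive neighbor sets
        ind = sp.csr_matrix(
            (
                np.ones(n * (n_neighbors + 1)),
                (
                    np.repeat(np.arange(n), n_neighbors + 1),
                    np.concatenate(
                        [neigh, np.arange(n)[:, None]], axis=1
                    ).ravel(),
                ),
            ),
            shape=(n, n),
        )
        ind.data[:] = 1  # duplicates collapse to membership
        inter = np.asarray(
            ind[edges[:, 0]].multiply(ind[edges[:, 1]]).sum(axis=1)
        ).ravel()
        set_sizes = np.asarray(ind.sum(axis=1)).ravel()
        union = set_sizes[edges[:, 0]] + set_sizes[edges[:, 1]] - inter
        weights = inter / union
    elif weighting == "uniform":
        weights = np.ones(len(edges))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    g = ig.Graph(n=n, edges=[tuple(e) for e in edges], directed=False)
    g.es["weight"] = list(weights)
    return g


def community_cluster(
    graph: ig.Graph,
    method: str = "leiden",
    resolution: float = 1.0,
    seed: int = 0,
) -> Partition:
    """Modularity-based community detection on a weighted cell graph.

    ``leiden`` uses the RB-configuration quality with the given resolution;
    ``louvain`` uses igraph's multilevel algorithm.  Labels come back
    renumbered by decreasing cluster size and are reproducible given the
    seed.
    """
    if graph.vcount() == 0:
        raise ValueError("cannot cluster an empty graph")
    weights = graph.es["weight"] if "weight" in graph.es.attributes() else None
    if method == "leiden":
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            weights=weights,
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=-1,
        )
        labels = np.array(part.membership)
    elif method == "louvain":
        state = ig.set_random_number_generator
        state(random.Random(seed))
        try:
            part = graph.community_multilevel(
                weights=weights, resolution=resolution
            )
        finally:
            state(random)  # restore the module-level default RNG
        labels = np.array(part.membership)
    else:
        raise ValueError(f"unknown method {method!r}; use leiden or louvain")
    return Partition.from_labels(labels, relabel_by_size=True)
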