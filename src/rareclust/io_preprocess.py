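"""Loading, filtering and library-size normalization of UMI count matrices.

The in-memory convention everywhere in this package is cells x genes, stored
sparse (CSR).  10x Matrix Market triplets are written genes x cells on disk
and are transposed on load.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.io
import scipy.sparse as sp
import pandas as pd

__all__ = [
    "CountMatrix",
    "MatrixFormatError",
    "MatrixValidationError",
    "EmptyResultError",
    "load_counts",
    "write_counts",
    "filter_matrix",
    "normalize_per_cell",
]


class MatrixFormatError(ValueError):
    """A file required by the on-disk format is missing or malformed."""


class MatrixValidationError(ValueError):
    """The matrix content violates a CountMatrix invariant."""


class EmptyResultError(ValueError):
    """Filtering removed every cell or every gene."""


@dataclass
class CountMatrix:
    """A cells x genes UMI count matrix with barcode and gene identifiers.

    Parameters
    ----------
    values
        Sparse matrix, cells in rows, genes in columns. Raw matrices hold
        nonnegative integers; normalized ones hold nonnegative reals.
    cell_ids, gene_ids
        Unique identifiers for rows / columns.
    normalized
        False for raw UMI counts, True after :func:`normalize_per_cell`.
    gene_symbols
        Optional human-readable symbols carried alongside ``gene_ids``
        (10x features.tsv column 2); ``gene_ids`` remain the key.
    """

    values: sp.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]
    normalized: bool = False
    gene_symbols: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.values.eliminate_zeros()
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n, g = self.values.shape
        if n != len(self.cell_ids):
            raise MatrixValidationError(
                f"{n} rows but {len(self.cell_ids)} cell ids"
            )
        if g != len(self.gene_ids):
            raise MatrixValidationError(
                f"{g} columns but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise MatrixValidationError("duplicate cell barcodes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise MatrixValidationError("duplicate gene identifiers")
        if self.values.nnz and self.values.data.min() < 0:
            raise MatrixValidationError("negative expression values")
        if not self.normalized and self.values.nnz:
            if not np.allclose(self.values.data, np.round(self.values.data)):
                raise MatrixValidationError(
                    "raw count matrix contains non-integer values"
                )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


def _find(directory: str, stems: list[str]) -> str:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = os.path.join(directory, name)
            if os.path.exists(p):
                return p
    raise MatrixFormatError(
        f"10x directory {directory!r} is missing {stems[0]}"
    )


def _read_tsv(path: str) -> pd.DataFrame:
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        return pd.read_csv(fh, sep="\t", header=None, dtype=str)


def load_counts(path: str, format: str = "10x_mtx") -> CountMatrix:
    """Load a count matrix from a 10x MTX triplet or a dense CSV.

    ``10x_mtx`` expects a directory containing ``matrix.mtx``,
    ``barcodes.tsv`` and ``genes.tsv`` or ``features.tsv`` (optionally
    gzipped); the on-disk genes x cells orientation is transposed.  ``csv``
    expects cells in rows, a header row of gene names, and the first column
    holding cell names.
    """
    if format == "10x_mtx":
        if not os.path.isdir(path):
            raise MatrixFormatError(f"{path!r} is not a directory")
        mtx = _find(path, ["matrix.mtx"])
        barcodes = _find(path, ["barcodes.tsv"])
        feats = _find(path, ["features.tsv", "genes.tsv"])
        m = sp.csr_matrix(scipy.io.mmread(mtx)).T  # genes x cells on disk
        cell_ids = _read_tsv(barcodes)[0].tolist()
        ftab = _read_tsv(feats)
        gene_ids = ftab[0].tolist()
        symbols = ftab[1].tolist() if ftab.shape[1] > 1 else None
        return CountMatrix(m, cell_ids, gene_ids, gene_symbols=symbols)
    if format == "csv":
        if not os.path.exists(path):
            raise MatrixFormatError(f"no such file: {path!r}")
        df = pd.read_csv(path, index_col=0)
        return CountMatrix(
            sp.csr_matrix(df.to_numpy()),
            df.index.tolist(),
            df.columns.tolist(),
        )
    raise ValueError(f"unknown format {format!r}; use '10x_mtx' or 'csv'")


def write_counts(m: CountMatrix, path: str, format: str = "10x_mtx") -> None:
    """Write a CountMatrix in either supported format (inverse of load)."""
    if format == "10x_mtx":
        os.makedirs(path, exist_ok=True)
        vals = m.values.T.tocoo()  # genes x cells on disk
        if not m.normalized:
            vals = vals.astype(np.int64)
        scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), vals)
        with open(os.path.join(path, "barcodes.tsv"), "w") as fh:
            fh.write("\n".join(m.cell_ids) + "\n")
        with open(os.path.join(path, "features.tsv"), "w") as fh:
            syms = m.gene_symbols or m.gene_ids
            for gid, sym in zip(m.gene_ids, syms):
                fh.write(f"{gid}\t{sym}\tGene Expression\n")
    elif format == "csv":
        df = pd.DataFrame(m.dense(), index=m.cell_ids, columns=m.gene_ids)
        if not m.normalized:
            df = df.astype(np.int64)
        df.to_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")


def filter_matrix(
    m: CountMatrix,
    min_cells_per_gene: int = 10,
    min_genes_per_cell: int = 500,
) -> CountMatrix:
    """Drop lowly-covered genes, then poorly-covered cells.

    Keeps genes detected (count > 0) in at least ``min_cells_per_gene``
    cells, then — on the gene-filtered matrix — cells detecting at least
    ``min_genes_per_cell`` genes.  Identifier order is preserved.
    """
    if m.normalized:
        raise MatrixValidationError("filter raw counts before normalizing")
    if min_cells_per_gene < 0 or min_genes_per_cell < 0:
        raise ValueError("thresholds must be nonnegative")
    csc = m.values.tocsc()
    cells_per_gene = np.diff(csc.indptr)
    gene_keep = cells_per_gene >= min_cells_per_gene
    if not gene_keep.any():
        raise EmptyResultError("no gene passes min_cells_per_gene")
    sub = csc[:, gene_keep].tocsr()
    genes_per_cell = np.diff(sub.indptr)
    cell_keep = genes_per_cell >= min_genes_per_cell
    if not cell_keep.any():
        raise EmptyResultError("no cell passes min_genes_per_cell")
    gidx = np.flatnonzero(gene_keep)
    cidx = np.flatnonzero(cell_keep)
    return CountMatrix(
        sub[cell_keep],
        [m.cell_ids[i] for i in cidx],
        [m.gene_ids[j] for j in gidx],
        normalized=False,
        gene_symbols=(
            [m.gene_symbols[j] for j in gidx] if m.gene_symbols else None
        ),
    )


def normalize_per_cell(m: CountMatrix, target_sum: float = 1e4) -> CountMatrix:
    """Scale every cell so its total count equals ``target_sum``.

    Preserves the zero pattern and within-cell expression ratios exactly.
    """
    if m.normalized:
        raise MatrixValidationError("matrix is already normalized")
    totals = np.asarray(m.values.sum(axis=1)).ravel()
    if (totals <= 0).any():
        raise MatrixValidationError(
            "cells with zero total count present; run filter_matrix with "
            "min_genes_per_cell >= 1 first"
        )
    scale = sp.diags(target_sum / totals)
    return replace(m, values=sp.csr_matrix(scale @ m.values), normalized=True)
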