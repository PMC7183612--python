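"""Fano-factor highly-variable-gene selection and PCA for the common branch."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io_preprocess import CountMatrix

__all__ = ["fano_factor", "fano_stats", "select_hvg", "pca_embed"]

EXACT_SVD_MAX_CELLS = 5000


def fano_factor(values) -> float:
    """Sample variance (N-1 denominator) over mean; Poisson data gives ~1."""
    x = np.asarray(values, dtype=float)
    mean = x.mean()
    if mean <= 0:
        raise ValueError("Fano factor is undefined for zero-mean data")
    return float(x.var(ddof=1) / mean)


def fano_stats(m: CountMatrix) -> pd.DataFrame:
    """Per-gene mean, variance and Fano factor on the (counts-scale) matrix.

    Genes with zero mean are excluded — their Fano factor is undefined.
    """
    dense = m.dense()
    means = dense.mean(axis=0)
    keep = means > 0
    variances = dense[:, keep].var(axis=0, ddof=1)
    return pd.DataFrame(
        {
            "gene_id": [g for g, k in zip(m.gene_ids, keep) if k],
            "mean": means[keep],
            "variance": variances,
            "fano": variances / means[keep],
        }
    )


def select_hvg(
    stats_df: pd.DataFrame,
    method: str = "top_n",
    n_top: int = 2000,
    z_cutoff: float = 0.5,
    n_bins: int = 20,
) -> list[str]:
    """Highly variable genes by Fano factor.

    ``top_n`` takes the ``n_top`` largest Fano factors (ties broken by input
    order).  ``dispersion_bins`` z-scores the Fano factor within ``n_bins``
    equal-frequency mean-expression bins and keeps genes with z > ``z_cutoff``
    — the binning removes the mean-dispersion trend the way standard
    single-cell toolkits do.
    """
    df = stats_df
    if method == "top_n":
        if n_top > len(df):
            warnings.warn(
                f"n_top={n_top} exceeds the {len(df)} available genes; "
                "selecting all",
                stacklevel=2,
            )
            n_top = len(df)
        # stable sort on negated fano keeps input order among ties
        order = np.argsort(-df["fano"].to_numpy(), kind="stable")[:n_top]
        sel = np.zeros(len(df), dtype=bool)
        sel[order] = True
    elif method == "dispersion_bins":
        fano = df["fano"].to_numpy(dtype=float)
        bins = pd.qcut(df["mean"], q=n_bins, labels=False, duplicates="drop")
        z = np.zeros(len(df))
        for b in np.unique(bins):
            mask = bins == b
            sd = fano[mask].std(ddof=1) if mask.sum() > 1 else 0.0
            if sd > 0:
                z[mask] = (fano[mask] - fano[mask].mean()) / sd
        sel = z > z_cutoff
    else:
        raise ValueError(f"unknown HVG method {method!r}")
    df["selected"] = sel
    return df.loc[sel, "gene_id"].tolist()


def pca_embed(
    m: CountMatrix,
    n_components: int = 50,
    log_transform: bool = True,
    scale: bool = True,
    seed: int = 0,
) -> np.ndarray:
    """Embed cells (rows) of an HVG-restricted matrix into PC space.

    Optionally log1p-transforms and per-gene standardizes (clipped at +-10).
    Uses exact SVD up to 5000 cells, seeded randomized SVD above, so results
    are deterministic either way.
    """
    X = m.dense().astype(float)
    max_nc = min(X.shape) - 1
    if n_components > max_nc:
        raise ValueError(
            f"n_components={n_components} too large; at most {max_nc} for a "
            f"{X.shape[0]} x {X.shape[1]} matrix"
        )
    if log_transform:
        X = np.log1p(X)
    if scale:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = np.clip((X - mu) / sd, -10, 10)
    solver = "full" if X.shape[0] <= EXACT_SVD_MAX_CELLS else "randomized"
    pca = PCA(n_components=n_components, svd_solver=solver, random_state=seed)
    return pca.fit_transform(X)


def write_hvg_table(stats_df: pd.DataFrame, path: str) -> None:
    stats_df.to_csv(path, sep="\t", index=False)
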