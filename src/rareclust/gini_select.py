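"""Gini-index feature selection for rare-population marker genes.

A gene expressed highly in a small subset of cells has an unequal
expression distribution and hence a high Gini index.  Because the Gini
index also rises as overall expression falls, raw values are normalized
against maximum expression with a two-step LOESS fit; genes far above the
fitted trend (large positive residual, small upper-tail p-value) are the
candidate rare-population markers.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_preprocess import CountMatrix

__all__ = [
    "gini_index",
    "gene_gini_stats",
    "loess_normalize_gini",
    "select_high_gini",
]

_MAD_TO_SD = 1.4826  # normal-consistency factor for the MAD

MIN_GENES_FOR_LOESS = 30


def gini_index(values) -> float:
    """Population Gini coefficient of a nonnegative vector.

    Twice the area between the diagonal and the empirical (step-function)
    Lorenz curve, identical to the normalized mean absolute difference
    sum_ij |x_i - x_j| / (2 N^2 xbar).  Computed from the sorted vector in
    O(N log N).  Lies in [0, 1).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d vector of length >= 2")
    if (x < 0).any():
        raise ValueError("negative values have no Lorenz curve")
    total = x.sum()
    if total == 0:
        raise ValueError("Gini index is undefined for an all-zero vector")
    n = x.size
    xs = np.sort(x)
    ranks = np.arange(1, n + 1)
    return float(2.0 * (ranks * xs).sum() / (n * total) - (n + 1) / n)


def _gini_by_column(dense: np.ndarray) -> np.ndarray:
    """Vectorized column-wise Gini (columns must have positive sums)."""
    n = dense.shape[0]
    xs = np.sort(dense, axis=0)
    ranks = np.arange(1, n + 1, dtype=float)[:, None]
    totals = xs.sum(axis=0)
    return 2.0 * (ranks * xs).sum(axis=0) / (n * totals) - (n + 1) / n


def gene_gini_stats(m: CountMatrix, log_offset: float = 0.1) -> pd.DataFrame:
    """Per-gene Gini index and log2 maximum expression.

    Computed on the normalized matrix.  Genes with all-zero expression
    (possible only if the matrix was not filtered) are excluded.
    Returns a DataFrame with columns ``gene_id, gini, log_max_expr``.
    """
    dense = m.dense()
    nonzero = dense.sum(axis=0) > 0
    dense = dense[:, nonzero]
    gene_ids = [g for g, keep in zip(m.gene_ids, nonzero) if keep]
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "gini": _gini_by_column(dense),
            "log_max_expr": np.log2(dense.max(axis=0) + log_offset),
        }
    )


def loess_normalize_gini(
    stats_df: pd.DataFrame,
    span: float = 0.9,
    outlier_p: float = 0.05,
    robust: bool = True,
) -> pd.DataFrame:
    """Two-step LOESS normalization of Gini indices against expression.

    Step A fits LOESS of ``gini`` on ``log_max_expr`` over all genes and
    screens for outliers: residuals are given one-sided upper-tail p-values
    under a normal fit, and genes with p < ``outlier_p`` are set aside.
    Step B refits LOESS on the remaining (null) genes only, so strong
    rare-population markers cannot drag the trend toward themselves.  The
    final ``norm_gini`` is the residual from the refit trend, and
    ``p_value`` its upper tail under a normal whose location/scale are the
    residual median and MAD x 1.4826 (or mean/sd when ``robust=False``).
    """
    df = stats_df.copy()
    n = len(df)
    if n < MIN_GENES_FOR_LOESS:
        raise ValueError(
            f"{n} genes is too few for LOESS normalization "
            f"(need >= {MIN_GENES_FOR_LOESS}); supply more genes or widen "
            "the upstream filters"
        )
    x = df["log_max_expr"].to_numpy(dtype=float)
    y = df["gini"].to_numpy(dtype=float)

    # Step A: trend over all genes, normal screen on residuals.
    fit_a = lowess(y, x, frac=span, return_sorted=False)
    resid_a = y - fit_a
    mu_a, sd_a = resid_a.mean(), resid_a.std(ddof=1)
    if sd_a == 0:
        sd_a = 1.0  # flat residuals: no gene can be an outlier
    p_a = stats.norm.sf(resid_a, loc=mu_a, scale=sd_a)
    null = p_a >= outlier_p

    # Step B: refit on null genes, predict everywhere by interpolation.
    if null.sum() >= MIN_GENES_FOR_LOESS:
        grid = lowess(y[null], x[null], frac=span, return_sorted=True)
        pred = np.interp(x, grid[:, 0], grid[:, 1])
    else:  # degenerate: almost everything flagged, keep the first fit
        pred = fit_a
    norm_gini = y - pred

    if robust:
        loc = np.median(norm_gini)
        scale = _MAD_TO_SD * np.median(np.abs(norm_gini - loc))
    else:
        loc, scale = norm_gini.mean(), norm_gini.std(ddof=1)
    if scale == 0:
        scale = np.finfo(float).tiny
    df["norm_gini"] = norm_gini
    df["p_value"] = stats.norm.sf(norm_gini, loc=loc, scale=scale)
    return df


def select_high_gini(
    stats_df: pd.DataFrame,
    gini_threshold: float = 0.6,
    p_threshold: float = 1e-4,
) -> list[str]:
    """Genes with Gini index >= ``gini_threshold`` AND p < ``p_threshold``.

    The Gini bound is inclusive, the p-value bound strict.  Adds/overwrites
    a boolean ``selected`` column on ``stats_df`` and returns the selected
    gene ids in input order.
    """
    sel = (stats_df["gini"] >= gini_threshold) & (
        stats_df["p_value"] < p_threshold
    )
    stats_df["selected"] = sel.to_numpy()
    genes = stats_df.loc[sel, "gene_id"].tolist()
    if not genes:
        warnings.warn(
            "no gene passed the high-Gini selection; the rare-cluster "
            "branch has no features",
            stacklevel=2,
        )
    return genes


def write_gini_table(stats_df: pd.DataFrame, path: str) -> None:
    cols = ["gene_id", "gini", "log_max_expr", "norm_gini", "p_value",
            "selected"]
    stats_df[[c for c in cols if c in stats_df]].to_csv(
        path, sep="\t", index=False
    )
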