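"""Preprocessing: quantile normalization, replicate averaging, gene centering.

Input is a positive linear-scale expression matrix E_{g,m,r} (genes x replicated
samples).  The SOM trains on the gene-centered log10 differential expression

    de_{g,m} = e_{g,m} - <e_g>,     e_{g,m} = <log10 E_{g,m,r}>_r,

i.e. each gene's replicate-averaged log expression relative to its mean over
all conditions.  Replicate-level standard deviations are kept as a side product
because the shrinkage-t error model (see :mod:`somportraits.diffexpr`) pools
them along the expression axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LogExpression",
    "read_expression",
    "read_condition_map",
    "quantile_normalize",
    "log_and_average",
    "center_genes",
    "preprocess",
]


@dataclass
class LogExpression:
    """Replicate-averaged log10 expression with per-condition replicate SDs.

    Attributes
    ----------
    values : DataFrame, genes x conditions
        e_{g,m}, the mean over replicates of log10 expression.
    sigma : DataFrame or None
        Population standard deviation of log10 expression over replicates,
        sqrt(<(e_r - <e>)^2>_r).  ``None`` when every condition has a single
        replicate (no within-condition variance is estimable).
    n_replicates : Series
        Replicate count R_m per condition.
    """

    values: pd.DataFrame
    sigma: pd.DataFrame | None
    n_replicates: pd.Series


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV/CSV (first column = gene id, header = samples)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        raise ValueError("duplicate gene ids in expression matrix")
    return df


def read_condition_map(path) -> pd.Series:
    """Read a two-column sample -> condition annotation TSV."""
    ann = pd.read_csv(path, sep="\t", index_col=0)
    return ann.iloc[:, 0]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common reference distribution.

    The reference is the row-wise mean of the column-sorted values; tied values
    within a column receive the mean of the reference values at their rank
    positions (average-rank dialect).  Idempotent.
    """
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in input to quantile normalization")
    n, m = values.shape
    if n < 2 or m < 2:
        raise ValueError("quantile normalization needs at least 2 genes and 2 samples")
    reference = np.sort(values, axis=0).mean(axis=1)
    # average ranks (1-based); interpolate the reference at fractional ranks
    out = np.empty_like(values)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(m):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty(n)
        ranks[order] = grid
        # average ranks over ties
        sorted_col = col[order]
        _, inv, counts = np.unique(sorted_col, return_inverse=True, return_counts=True)
        sums = np.bincount(inv, weights=grid)
        avg = (sums / counts)[inv]
        ranks[order] = avg
        out[:, j] = np.interp(ranks, grid, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log_and_average(raw: pd.DataFrame, conditions: pd.Series) -> LogExpression:
    """log10-transform and average replicates per condition.

    Parameters
    ----------
    raw : DataFrame, genes x samples
        Positive linear-scale expression E_{g,m,r}; columns are sample ids.
    conditions : Series
        Maps each sample column to its condition id.

    Returns the replicate-averaged log expression plus the per-condition
    population SD of the logged replicates (``sigma`` is None when every
    condition has one replicate).
    """
    missing = [c for c in raw.columns if c not in conditions.index]
    if missing:
        raise ValueError(f"samples without condition annotation: {missing}")
    bad = raw.le(0) | ~np.isfinite(raw)
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-positive expression value for gene {raw.index[g]!r} in sample "
            f"{raw.columns[s]!r}; linear-scale input must be > 0"
        )
    logged = np.log10(raw)
    groups = conditions.loc[raw.columns]
    cond_order = list(dict.fromkeys(groups))  # first-appearance order
    values = logged.T.groupby(groups).mean().T[cond_order]
    counts = groups.value_counts()[cond_order].rename("n_replicates")
    if (counts > 1).any():
        sigma = logged.T.groupby(groups).std(ddof=0).T[cond_order]
    else:
        sigma = None
    return LogExpression(values=values, sigma=sigma, n_replicates=counts)


def center_genes(e: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's cross-condition mean: de_{g,m} = e_{g,m} - <e_g>_m."""
    if e.shape[1] < 2:
        raise ValueError("gene centering needs at least 2 conditions")
    return e.sub(e.mean(axis=1), axis=0)


def preprocess(
    raw: pd.DataFrame,
    conditions: pd.Series,
    scale: str = "linear",
    normalize: bool = True,
) -> tuple[pd.DataFrame, LogExpression]:
    """Full preprocessing chain: (quantile-normalize ->) log+average -> center.

    ``scale`` declares the input scale: ``"linear"`` (logged here) or
    ``"log10"`` (log step skipped; values used as-is).  Normalization is
    applied to the sample columns before replicate averaging.

    Returns ``(delta, log_expression)`` where ``delta`` is the gene-centered
    differential expression matrix the SOM trains on.
    """
    if scale not in ("linear", "log10"):
        raise ValueError(f"unknown scale {scale!r}")
    if scale == "log10":
        raw = 10.0 ** raw
    if normalize:
        logged = np.log10(raw)
        logged = quantile_normalize(logged)
        raw = 10.0 ** logged
    log_expr = log_and_average(raw, conditions)
    delta = center_genes(log_expr.values)
    return delta, log_expr
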