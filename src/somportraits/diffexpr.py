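"""Differential expression: FC / WAD / shrinkage-t scores, fdr/Fdr, rankings.

Three per-gene-per-sample scores are computed on the centered log10 matrix:

* ``logFC`` — the differential expression de_{g,m} itself;
* ``WAD`` — de weighted by the gene's relative expression position within the
  sample, w = (de - min de) / (max de - min de), so strongly expressed genes
  are up-weighted ("strong signals are better signals");
* shrinkage ``t`` — de divided by a standard error whose variance blends the
  gene's own replicate variance with a locally pooled error (LPE) curve,
  sigma_shr^2 = lambda*sigma^2 + (1-lambda)*sigma_LPE(e)^2.  The LPE curve is
  the moving-window mean of the replicate SDs along the expression axis and
  captures the inflation of the log-scale error at low expression.

p-values come from a two-sided Student t with R_m - 1 degrees of freedom
(normal approximation with the pure LPE error when a condition has a single
replicate).  The p-value ensemble of a sample is decomposed into a uniform
null fraction eta0 and a differentially expressed rest with a Grenander-type
monotone density estimate, yielding the local fdr(p) = eta0/rho(p) and the
tail-area Fdr(p) = eta0*p/F(p), with the boundary identities fdr(1) = 1,
Fdr(1) = eta0 and Fdr(0) = fdr(0); %DE = 1 - eta0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .som import GeneAssignment
from .spots import Spot

__all__ = [
    "LPECurve",
    "FdrEstimate",
    "fc_score",
    "wad_score",
    "lpe_curve",
    "shrinkage_t",
    "estimate_fdr",
    "rank_genes",
    "metagene_significance",
    "spot_significance",
    "rank_product",
    "score_table",
]


def fc_score(delta: pd.DataFrame) -> pd.DataFrame:
    """The log10 fold change vs the gene's cross-sample mean (identity on de)."""
    return delta.copy()


def wad_score(delta: pd.DataFrame) -> pd.DataFrame:
    """Weighted average difference: WAD = w * de, w scaled to [0,1] per sample."""
    lo = delta.min(axis=0)
    hi = delta.max(axis=0)
    rng = hi - lo
    if (rng <= 0).any():
        bad = rng.index[rng <= 0][0]
        raise ValueError(f"constant differential expression in sample {bad!r}; WAD undefined")
    w = delta.sub(lo, axis=1).div(rng, axis=1)
    return w * delta


@dataclass
class LPECurve:
    """Step-interpolated mean replicate SD vs log-expression, per sample."""

    e_sorted: np.ndarray  # expression knots (ascending)
    sigma_mean: np.ndarray  # window-mean SD at each knot
    window: int

    def __call__(self, e) -> np.ndarray:
        """Evaluate by step interpolation (nearest knot below, clamped)."""
        idx = np.clip(np.searchsorted(self.e_sorted, np.asarray(e, float), side="right") - 1,
                      0, len(self.e_sorted) - 1)
        return self.sigma_mean[idx]


def lpe_curve(e: np.ndarray, sigma: np.ndarray, window: int = 200) -> LPECurve:
    """Locally pooled error: moving-window mean of sigma in e-order.

    For each gene the pooled SD is the mean of the ``window`` replicate SDs
    nearest in expression order (centered window, truncated symmetrically at
    the edges so it always covers exactly ``window`` genes).
    """
    e = np.asarray(e, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    ok = np.isfinite(e) & np.isfinite(sigma)
    e, sigma = e[ok], sigma[ok]
    n = len(e)
    if window > n:
        raise ValueError(f"LPE window ({window}) exceeds number of genes with SDs ({n})")
    order = np.argsort(e, kind="mergesort")
    es, ss = e[order], sigma[order]
    csum = np.concatenate([[0.0], np.cumsum(ss)])
    starts = np.clip(np.arange(n) - (window - 1) // 2, 0, n - window)
    means = (csum[starts + window] - csum[starts]) / window
    return LPECurve(e_sorted=es, sigma_mean=means, window=window)


def shrinkage_t(
    delta: pd.DataFrame,
    e: pd.DataFrame,
    sigma: pd.DataFrame | None,
    curves: dict[str, LPECurve],
    n_replicates: pd.Series,
    lam: float = 0.5,
    se_mode: str = "approx",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Shrinkage t-score, its standard error and two-sided p-values.

    ``se_mode="approx"`` (default) uses SE = sigma_shr / sqrt(R_m); ``"exact"``
    adds the variance contribution of the cross-sample mean,
    SE^2 = sigma_shr^2/R_m + <sigma_shr^2>_m / sum_m R_m.
    Conditions with R_m = 1 carry no own variance: there the error is the pure
    LPE estimate and the p-value uses the normal approximation.

    Returns ``(t, se, p)`` DataFrames aligned with ``delta``.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("shrinkage weight lambda must be in [0, 1]")
    if se_mode not in ("approx", "exact"):
        raise ValueError(f"unknown se_mode {se_mode!r}")
    conds = list(delta.columns)
    n_rep = n_replicates.loc[conds].to_numpy(dtype=float)
    sig_lpe = np.column_stack([curves[c](e[c].to_numpy()) for c in conds])
    if sigma is not None:
        own_var = sigma[conds].to_numpy(dtype=float) ** 2
        # single-replicate conditions have no own variance estimate -> pure LPE
        lam_eff = np.where(n_rep > 1, lam, 0.0)[None, :]
    else:
        own_var = np.zeros_like(sig_lpe)
        lam_eff = np.zeros((1, len(conds)))
    var_shr = lam_eff * own_var + (1.0 - lam_eff) * sig_lpe**2
    se2 = var_shr / n_rep[None, :]
    if se_mode == "exact":
        se2 = se2 + var_shr.mean(axis=1, keepdims=True) / n_rep.sum()
    se = np.sqrt(se2)
    d = delta.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, d / se, np.where(d == 0, 0.0, np.inf * np.sign(d)))
    df_per_cond = np.maximum(n_rep - 1, 0)
    p = np.empty_like(t)
    for j, dfj in enumerate(df_per_cond):
        tj = t[:, j]
        if dfj >= 1:
            p[:, j] = 2.0 * stats.t.sf(np.abs(tj), dfj)
        else:
            p[:, j] = 2.0 * stats.norm.sf(np.abs(tj))
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((se == 0) & (d == 0), 1.0, p)
    idx, cols = delta.index, delta.columns
    return (pd.DataFrame(t, idx, cols), pd.DataFrame(se, idx, cols),
            pd.DataFrame(np.clip(p, 0.0, 1.0), idx, cols))


@dataclass
class FdrEstimate:
    """Grenander-type decomposition of a p-value ensemble.

    ``knots``/``rho`` define the non-increasing step density; ``eta0`` is its
    level at p = 1 (the null fraction), ``pct_de = 1 - eta0``.
    """

    eta0: float
    knots: np.ndarray = field(repr=False)  # segment right edges, ascending, last = 1
    rho: np.ndarray = field(repr=False)  # density level on each segment
    cdf_knots: np.ndarray = field(repr=False)  # LCM cdf value at each right edge
    n: int = 0

    @property
    def pct_de(self) -> float:
        return 1.0 - self.eta0

    def density(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        idx = np.clip(np.searchsorted(self.knots, p, side="left"), 0, len(self.knots) - 1)
        return self.rho[idx]

    def fdr(self, p) -> np.ndarray:
        """Local false discovery rate eta0/rho(p), capped at 1; fdr(1) = 1."""
        return np.minimum(self.eta0 / self.density(p), 1.0)

    def cdf(self, p) -> np.ndarray:
        # the (unfloored) least concave majorant itself, linear between knots
        return np.interp(np.asarray(p, dtype=float), np.concatenate([[0.0], self.knots]),
                         np.concatenate([[0.0], self.cdf_knots]))

    def Fdr(self, p) -> np.ndarray:
        """Tail-area FDR eta0*p/F(p); Fdr(1) = eta0 and Fdr(0) = fdr(0)."""
        p = np.asarray(p, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.eta0 * p / self.cdf(p)
        out = np.where(p == 0, self.eta0 / self.rho[0], out)
        return np.minimum(out, 1.0)


def _concave_majorant(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vertex arrays of the least concave majorant of the points (x, y)."""
    hx = [x[0]]
    hy = [y[0]]
    for xi, yi in zip(x[1:], y[1:]):
        while len(hx) >= 2:
            # pop last vertex while it lies below the chord -> keep slopes decreasing
            if (hy[-1] - hy[-2]) * (xi - hx[-1]) <= (yi - hy[-1]) * (hx[-1] - hx[-2]):
                hx.pop(); hy.pop()
            else:
                break
        hx.append(xi)
        hy.append(yi)
    return np.asarray(hx), np.asarray(hy)


def estimate_fdr(pvalues, background_lambda: float = 0.5) -> FdrEstimate:
    """Grenander decomposition of p-values into null and alternative mass.

    The density estimate is the slope of the least concave majorant of the
    empirical CDF on [0, 1] (anchored at (0,0) and (1,1)), the
    maximum-likelihood non-increasing density.  The raw Grenander slope
    vanishes beyond the largest observed p-value, so the null level is read
    from the upper tail instead: under the assumption that differential
    expression vanishes near p = 1, the density there is flat at
    eta0 = #{p > lambda} / (n * (1 - lambda)); the Grenander density is
    floored at that level, which makes rho(1) = eta0 and hence fdr(1) = 1
    exactly.  The tail-area Fdr uses the (unflooored) majorant CDF, so
    Fdr(1) = eta0 and Fdr(p) <= fdr(p) hold by construction.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < 10:
        raise ValueError("need at least 10 p-values for an fdr estimate")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    lam = background_lambda
    eta0 = float(np.clip((p > lam).sum() / (n * (1.0 - lam)), 1e-8, 1.0))
    xs, counts = np.unique(np.sort(p), return_counts=True)
    ys = np.cumsum(counts) / n
    x = np.concatenate([[0.0], xs])
    y = np.concatenate([[0.0], ys])
    if x[-1] < 1.0:
        x = np.concatenate([x, [1.0]])
        y = np.concatenate([y, [1.0]])
    else:
        y[-1] = 1.0
    hx, hy = _concave_majorant(x, y)
    rho = np.maximum(np.diff(hy) / np.diff(hx), eta0)
    knots = hx[1:]
    return FdrEstimate(eta0=eta0, knots=knots, rho=rho, cdf_knots=hy[1:], n=n)


def rank_genes(scores: pd.Series, scope=None) -> pd.Series:
    """Rank genes by descending score magnitude; ties by gene id (lexicographic).

    ``scope`` restricts the ranking to a gene subset (e.g. a spot gene list);
    ranks run 1..N_list within the scope.
    """
    s = scores if scope is None else scores.loc[list(scope)]
    if len(s) == 0:
        raise ValueError("empty ranking scope")
    order = sorted(s.index, key=lambda g: (-abs(s[g]), str(g)))
    return pd.Series(np.arange(1, len(order) + 1), index=order, name="rank")


def metagene_significance(assignment: GeneAssignment, stat: pd.Series) -> np.ndarray:
    """Arithmetic mean of a per-gene statistic over each minicluster (NaN if empty)."""
    k = len(assignment.clusters)
    vals = stat.loc[assignment.bmu.index].to_numpy(dtype=float)
    sums = np.bincount(assignment.bmu.to_numpy(), weights=vals, minlength=k)
    with np.errstate(invalid="ignore"):
        return sums / np.where(assignment.sizes > 0, assignment.sizes, np.nan)


def spot_significance(spot: Spot, assignment: GeneAssignment, stat: pd.Series) -> float:
    """Mean statistic over all genes of all spot metagenes."""
    genes = [g for k in spot.tiles for g in assignment.clusters[k]]
    if not genes:
        raise ValueError(f"spot {spot.label!r} contains no genes")
    return float(stat.loc[genes].mean())


def rank_product(values: pd.DataFrame, ascending: bool = False) -> pd.Series:
    """Geometric mean of the per-sample ranks: RP_g = (prod_m rank_{g,m})^(1/M).

    By default genes are ranked descending per sample (rank 1 = largest value),
    so a small RP marks consistently top-ranked genes.  Ties share the average
    rank.
    """
    ranks = values.rank(axis=0, ascending=ascending, method="average")
    return np.exp(np.log(ranks).mean(axis=1)).rename("rank_product")


def score_table(
    delta: pd.DataFrame,
    e: pd.DataFrame,
    sigma: pd.DataFrame | None,
    n_replicates: pd.Series,
    lam: float = 0.5,
    lpe_window: int = 200,
    se_mode: str = "approx",
) -> dict[str, pd.DataFrame]:
    """All per-gene-per-sample scores in one pass.

    Returns a dict with ``logFC``, ``WAD``, ``t``, ``se``, ``p`` DataFrames
    (genes x conditions) plus per-sample LPE curves under ``"lpe"``.
    """
    window = min(lpe_window, max(len(delta) // 2, 3))
    if sigma is not None:
        curves = {c: lpe_curve(e[c].to_numpy(), sigma[c].to_numpy(), window)
                  for c in delta.columns}
    else:
        # no replicate SDs anywhere: fall back to a constant pseudo-error from
        # the per-gene profile spread so the t-score stays defined
        fallback = float(np.median(delta.std(axis=1, ddof=0))) or 1.0
        curves = {c: LPECurve(np.array([0.0]), np.array([fallback]), 1)
                  for c in delta.columns}
    t, se, p = shrinkage_t(delta, e, sigma, curves, n_replicates, lam, se_mode)
    return {"logFC": fc_score(delta), "WAD": wad_score(delta), "t": t, "se": se,
            "p": p, "lpe": curves}
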