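"""Concordance diagnostics for alternative ranked gene lists.

CAT(r) ("correspondence at the top") is the fraction of genes shared by the
top r of two lists; for independent random rankings its expectation is the
hypergeometric mean r/N.  p-CAT(r) cumulates the log10 shrinkage-t p-values of
the top-r genes of a list, so the t-ordered list is the pointwise minimum;
Delta p-CAT is the (non-negative) excess of an alternative ordering over that
optimum.  The RC plot flags, per rank, whether the gene's rank in the other
list agrees within a window (default +/- 20 positions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CatCurve", "cat", "p_cat", "delta_p_cat", "rank_correspondence"]


@dataclass
class CatCurve:
    """CAT fractions per rank with the r/N null reference attached."""

    r: np.ndarray
    cat: np.ndarray
    null: np.ndarray  # r/N

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r": self.r, "CAT": self.cat, "null": self.null})


def _check_universe(list_a, list_b) -> int:
    sa, sb = set(list_a), set(list_b)
    if len(sa) != len(list_a) or len(sb) != len(list_b):
        raise ValueError("duplicate gene ids in a ranked list")
    if sa != sb:
        raise ValueError("ranked lists must share the same gene universe")
    return len(sa)


def cat(list_a, list_b, r_max: int | None = None) -> CatCurve:
    """CAT(r) = |top_r(A) ∩ top_r(B)| / r for r = 1..r_max."""
    n = _check_universe(list_a, list_b)
    if r_max is None:
        r_max = n
    elif r_max > n:
        warnings.warn(f"r_max {r_max} exceeds list length {n}; clamped", stacklevel=2)
        r_max = n
    in_a: set = set()
    in_b: set = set()
    common = np.empty(r_max)
    count = 0
    for r in range(r_max):
        ga, gb = list_a[r], list_b[r]
        in_a.add(ga)
        in_b.add(gb)
        # a gene becomes common at round max(rank_A, rank_B), on the side
        # where it was just added; the guard avoids double counting ga == gb
        if ga in in_b:
            count += 1
        if gb != ga and gb in in_a:
            count += 1
        common[r] = count
    r = np.arange(1, r_max + 1)
    return CatCurve(r=r, cat=common / r, null=r / n)


def p_cat(gene_list, pvalues: pd.Series, r_max: int | None = None) -> np.ndarray:
    """Cumulative log10 p of the top-r genes of a list (non-increasing in r)."""
    if r_max is None:
        r_max = len(gene_list)
    top = list(gene_list[:r_max])
    missing = [g for g in top if g not in pvalues.index]
    if missing:
        raise ValueError(f"no p-value for listed gene(s), e.g. {missing[0]!r}")
    p = pvalues.loc[top].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log10(np.maximum(p, np.finfo(float).tiny))
    return np.cumsum(logs)


def delta_p_cat(alt_list, ref_t_list, pvalues: pd.Series,
                r_max: int | None = None) -> np.ndarray:
    """p-CAT(alt) - p-CAT(t-ordered reference); >= 0 at every rank."""
    _check_universe(alt_list, ref_t_list)
    if r_max is None:
        r_max = len(alt_list)
    return p_cat(alt_list, pvalues, r_max) - p_cat(ref_t_list, pvalues, r_max)


def rank_correspondence(list_a, list_b, window: int = 20) -> np.ndarray:
    """Boolean per rank of A: does the gene's rank in B agree within +/- window?"""
    _check_universe(list_a, list_b)
    pos_b = {g: i + 1 for i, g in enumerate(list_b)}
    ranks_a = np.arange(1, len(list_a) + 1)
    ranks_in_b = np.array([pos_b[g] for g in list_a])
    return np.abs(ranks_a - ranks_in_b) <= window
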