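"""Global-criterion gene sets: highly expressed, top-ranked, absent, housekeepers.

These sets are defined by absolute expression criteria rather than GO
membership: the top fraction of maximal differential expression, the top of
the cross-sample rank-product list, genes never (pc = 0 everywhere) or always
(pc = 1 everywhere) detected, and the top fraction by mean expression.  They
feed straight back into the gene-set machinery (population maps, GSZ
profiles, overrepresentation).  A correlation filter distills tissue-specific
sets from spots by keeping only members tightly correlated (Pearson r beyond
a threshold) with their own metagene profile.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .diffexpr import rank_product
from .genesets import GeneSet
from .som import GeneAssignment, SOMGrid
from .spots import Spot

__all__ = ["CRITERIA", "select_special_set", "correlation_filter_spot_set"]

CRITERIA = (
    "high_expression",
    "top_rank_product",
    "absent",
    "housekeeper_present",
    "housekeeper_mean",
)


def _top_fraction(scores: pd.Series, fraction: float) -> frozenset:
    n_take = max(1, int(round(fraction * len(scores))))
    order = sorted(scores.index, key=lambda g: (-scores[g], str(g)))
    return frozenset(order[:n_take])


def select_special_set(
    criterion: str,
    delta: pd.DataFrame | None = None,
    e: pd.DataFrame | None = None,
    present_calls: pd.DataFrame | None = None,
    fraction: float = 0.10,
) -> GeneSet:
    """Build one of the global-criterion gene sets.

    criterion:
      - ``high_expression``: top ``fraction`` by max-over-samples delta-e;
      - ``top_rank_product``: top ``fraction`` by ascending rank product of
        per-sample expression ranks (consistently top-ranked genes);
      - ``absent``: present call pc = 0 in every sample;
      - ``housekeeper_present``: pc = 1 in every sample;
      - ``housekeeper_mean``: top ``fraction`` by mean log expression.
    """
    if criterion == "high_expression":
        if delta is None:
            raise ValueError("high_expression needs the differential expression matrix")
        genes = _top_fraction(delta.max(axis=1), fraction)
    elif criterion == "top_rank_product":
        if e is None:
            raise ValueError("top_rank_product needs the log expression matrix")
        rp = rank_product(e)
        genes = _top_fraction(-rp, fraction)  # ascending RP = top-ranked
    elif criterion == "absent":
        if present_calls is None:
            raise ValueError("absent needs the present-call matrix")
        mask = present_calls.eq(0).all(axis=1)
        genes = frozenset(present_calls.index[mask])
    elif criterion == "housekeeper_present":
        if present_calls is None:
            raise ValueError("housekeeper_present needs the present-call matrix")
        mask = present_calls.eq(1).all(axis=1)
        genes = frozenset(present_calls.index[mask])
    elif criterion == "housekeeper_mean":
        if e is None:
            raise ValueError("housekeeper_mean needs the log expression matrix")
        genes = _top_fraction(e.mean(axis=1), fraction)
    else:
        raise ValueError(f"unknown criterion {criterion!r}; one of {CRITERIA}")
    if not genes:
        warnings.warn(f"criterion {criterion!r} selected no genes", stacklevel=2)
        genes = frozenset()
    return GeneSet(name=criterion, genes=genes, category="special") if genes else _empty(criterion)


class _EmptySet:
    """Stand-in for an empty selection (GeneSet forbids empty membership)."""

    def __init__(self, name):
        self.name = name
        self.genes = frozenset()
        self.category = "special"

    def __len__(self):
        return 0


def _empty(name: str) -> _EmptySet:
    return _EmptySet(name)


def correlation_filter_spot_set(
    spot: Spot,
    delta: pd.DataFrame,
    grid: SOMGrid,
    assignment: GeneAssignment,
    r_min: float = 0.8,
    name: str | None = None,
) -> GeneSet | _EmptySet:
    """Tissue-specific set: spot genes Pearson-correlated (> r_min) with their
    own metagene profile.

    Genes with a constant profile (correlation undefined) are excluded with a
    warning.
    """
    if not spot.genes:
        raise ValueError("spot has no genes")
    keep: list[str] = []
    dropped_constant = 0
    for g in spot.genes:
        prof = delta.loc[g].to_numpy(dtype=float)
        mg = grid.weights[int(assignment.bmu[g])]
        if prof.std() == 0 or mg.std() == 0:
            dropped_constant += 1
            continue
        r = np.corrcoef(prof, mg)[0, 1]
        if r > r_min:
            keep.append(g)
    if dropped_constant:
        warnings.warn(f"{dropped_constant} gene(s) with constant profile excluded "
                      "(correlation undefined)", stacklevel=2)
    set_name = name or f"spot_{spot.label}_{spot.source or 'sample'}"
    if not keep:
        warnings.warn(f"no spot gene passed the r > {r_min} filter", stacklevel=2)
        return _empty(set_name)
    return GeneSet(name=set_name, genes=frozenset(keep), category="tissue_specific")
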