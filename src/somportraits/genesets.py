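"""Gene-set overrepresentation (hypergeometric) and enrichment (GSZ score).

Overrepresentation of a set (size N_set) in a list (length N_list) drawn from
a universe of N genes is the hypergeometric tail probability of observing a
*stronger* overlap than the N_+ seen (strictly-greater tail; the conventional
inclusive tail is available behind a flag).

The GSZ score generalizes this: with per-gene scores S over the list, the
difference Delta_S = S_+ - S_- between set members and non-members is
standardized by its null mean and variance under random set membership
(hypergeometric moments), with a small-sample regularization that blends the
exact standard error with a floor SE_0 computed at minimum list/set sizes:

    GSZ = (Delta_S - E[Delta_S]) / sqrt(lambda*SE^2 + (1-lambda)*SE_0^2),
    lambda = 1 - min(1, (N_list_min/N_list) * (N_set_min/N_set)).

Two closed-form special cases serve as oracles: the full-list overexpression
Z (set mean vs grand mean) and the binary overrepresentation Z (observed vs
expected positives).  Permutation p-values draw size-matched random sets from
the universe.  Incoherent sets whose members carry cancelling positive and
negative scores are automatically damped because Delta_S sums signed scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .som import GeneAssignment
from .spots import Spot

__all__ = [
    "GeneSet",
    "GSZParams",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "hg_overrepresentation",
    "hypergeom_moments",
    "gsz",
    "gsz_full_list",
    "gsz_binary",
    "gsz_permutation_p",
    "metagene_overrepresentation_map",
    "spot_enrichment",
    "gene_set_profile",
    "top_three_heatmap",
]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene ids (GO term, pathway, or custom)."""

    name: str
    genes: frozenset
    category: str = "custom"
    description: str = ""

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GSZParams:
    """Regularization and permutation settings for the GSZ score."""

    n_list_min: int = 10
    n_set_min: int = 10
    n_permutations: int = 1000
    seed: int = 0
    tail: str = "two"  # "one" | "two"

    def validate(self) -> None:
        if self.n_list_min < 1 or self.n_set_min < 1:
            raise ValueError("minimum list/set sizes must be >= 1")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        if self.tail not in ("one", "two"):
            raise ValueError("tail must be 'one' or 'two'")


@dataclass
class EnrichmentResult:
    """Per (gene set x context) significance record."""

    set_name: str
    context: str
    hg_p: float | None = None
    gsz: float | None = None
    perm_p: float | None = None
    n_positive: int = 0
    rank: int = 0


def read_gmt(path, universe=None) -> list[GeneSet]:
    """Parse a GMT file (name TAB description TAB member...).

    Duplicate members collapse; with ``universe`` given, members are filtered
    to it and sets empty after filtering are dropped with a warning.
    """
    sets: list[GeneSet] = []
    universe = set(universe) if universe is not None else None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed GMT line (need >= 3 fields)")
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            genes = set(members)
            if universe is not None:
                genes &= universe
                if not genes:
                    warnings.warn(f"gene set {name!r} empty after universe filter; dropped",
                                  stacklevel=2)
                    continue
            sets.append(GeneSet(name=name, genes=frozenset(genes), description=desc))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description or s.category, *sorted(s.genes)]) + "\n")


def hg_overrepresentation(n: int, n_list: int, n_set: int, n_pos: int,
                          inclusive: bool = False) -> float:
    """Hypergeometric overrepresentation p-value of an overlap n_pos.

    Default is the strictly-greater tail P(X > N_+); ``inclusive=True`` gives
    the conventional P(X >= N_+).
    """
    if not (0 <= n_set <= n and 0 <= n_list <= n and
            max(0, n_list + n_set - n) <= n_pos <= min(n_list, n_set)):
        raise ValueError(
            f"impossible contingency margins N={n}, N_list={n_list}, "
            f"N_set={n_set}, N_+={n_pos}")
    k = n_pos - 1 if inclusive else n_pos
    return float(stats.hypergeom.sf(k, n, n_set, n_list))


def hypergeom_moments(n: int, n_list: int, n_set: int) -> tuple[float, float]:
    """Mean and variance of the positive-overlap count under random drawing."""
    mean = n_set * n_list / n
    var = mean * (1.0 - n_set / n) * ((n - n_list) / (n - 1)) if n > 1 else 0.0
    return mean, var


def _list_moments(s: np.ndarray) -> tuple[float, float]:
    # population (divide-by-N_list) mean and variance of the scores in the list
    return float(s.mean()), float(s.var())


def gsz(
    scores: pd.Series,
    gene_set: GeneSet,
    n_universe: int,
    params: GSZParams | None = None,
    lam: float | None = None,
    se_mode: str = "exact",
) -> float:
    """Regularized gene-set Z score of a scored gene list.

    ``scores`` holds the per-gene score S over the list (index = gene ids);
    ``n_universe`` is the total number N of analyzed genes.  ``lam`` overrides
    the size-penalty weight (None -> computed from the minimum settings).
    ``se_mode="exact"`` uses the exact null variance of Delta_S;
    ``"asymptotic"`` the large-N approximation.
    """
    params = params or GSZParams()
    params.validate()
    s = scores.to_numpy(dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite scores")
    n_list = len(s)
    n = n_universe
    in_set = scores.index.isin(gene_set.genes)
    n_set = len(gene_set)
    s_plus = float(s[in_set].sum())
    s_total = float(s.sum())
    delta_s = 2.0 * s_plus - s_total
    mean_s, var_s = _list_moments(s)
    npos_mean, npos_var = hypergeom_moments(n, n_list, n_set)
    e_delta = mean_s * (2.0 * npos_mean - n_list)
    if se_mode == "exact":
        if n_list > 1:
            se2 = 4.0 * (var_s * (npos_mean * (n_list - npos_mean) - npos_var)
                         / (n_list - 1) + mean_s**2 * npos_var)
        else:
            se2 = 4.0 * mean_s**2 * npos_var
    elif se_mode == "asymptotic":
        se2 = _se2_asymptotic(n, n_list, n_set, mean_s, var_s)
    else:
        raise ValueError(f"unknown se_mode {se_mode!r}")
    if lam is None:
        lam = 1.0 - min(1.0, (params.n_list_min / n_list) * (params.n_set_min / n_set))
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    se0_2 = _se2_asymptotic(n, params.n_list_min, params.n_set_min, mean_s, var_s)
    denom2 = lam * se2 + (1.0 - lam) * se0_2
    if denom2 <= 0:
        raise ValueError("zero GSZ denominator (degenerate scores and margins)")
    return float((delta_s - e_delta) / np.sqrt(denom2))


def _se2_asymptotic(n, n_list, n_set, mean_s, var_s) -> float:
    # large-N form of the Delta_S null variance; also defines the SE_0 floor
    # at the minimum list/set sizes
    return 4.0 * (n_set * n_list / n) * (
        var_s * (1.0 - n_set / n)
        + mean_s**2 * (1.0 - n_set / n) * (1.0 - n_list / n)
    )


def gsz_full_list(scores: pd.Series, gene_set: GeneSet,
                  finite_population: bool = False) -> float:
    """Overexpression Z of a set on the full gene list.

    Z = (<S>_set - <S>_all) / sqrt(var(S)_all / N_set)  (population variance).
    With ``finite_population=True`` the denominator carries the exact
    finite-population factor (N - N_set)/(N - 1), which makes the value the
    exact algebraic reduction of the general GSZ score at N_list = N.
    """
    s = scores.to_numpy(dtype=float)
    in_set = scores.index.isin(gene_set.genes)
    n_set = int(in_set.sum())
    if n_set == 0:
        raise ValueError("set does not intersect the scored universe")
    var_s = s.var()
    if var_s <= 0:
        raise ValueError("zero score variance; overexpression Z undefined")
    n = len(s)
    denom2 = var_s / n_set
    if finite_population:
        denom2 *= (n - n_set) / (n - 1)
    return float((s[in_set].mean() - s.mean()) / np.sqrt(denom2))


def gsz_binary(n: int, n_list: int, n_set: int, n_pos: int,
               short_list: bool = False) -> float:
    """Overrepresentation Z: observed vs expected positives, hypergeometric SD.

    ``short_list=True`` uses the simplified variance N_set*N_list/N valid for
    short lists and small sets.
    """
    mean, var = hypergeom_moments(n, n_list, n_set)
    if short_list:
        var = n_set * n_list / n
    if var <= 0:
        raise ValueError("zero overlap variance; binary Z undefined")
    return float((n_pos - mean) / np.sqrt(var))


def gsz_permutation_p(
    observed: float,
    scores: pd.Series,
    set_size: int,
    universe: list,
    params: GSZParams | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value from size-matched random sets drawn from the universe.

    p = (1 + #{|null| >= |obs|}) / (1 + B) for the two-tailed test; the
    one-tailed version compares signed values.
    """
    params = params or GSZParams()
    params.validate()
    rng = rng or np.random.default_rng(params.seed)
    universe = np.asarray(universe, dtype=object)
    b = params.n_permutations
    null = np.empty(b)
    for i in range(b):
        draw = rng.choice(universe, size=set_size, replace=False)
        null[i] = gsz(scores, GeneSet("null", frozenset(draw)), len(universe), params)
    if params.tail == "two":
        exceed = np.abs(null) >= abs(observed)
    else:
        exceed = null >= observed
    return float((1 + exceed.sum()) / (1 + b))


def metagene_overrepresentation_map(
    gene_set: GeneSet,
    assignment: GeneAssignment,
    inclusive: bool = False,
) -> np.ndarray:
    """Per-metagene hypergeometric p of the set in each minicluster.

    Sample-independent (the miniclusters are fixed); tiles containing no set
    member are NaN so portraits render them white.
    """
    n = assignment.n_genes
    n_set = int(assignment.bmu.index.isin(gene_set.genes).sum())
    k = len(assignment.clusters)
    hits = np.bincount(
        assignment.bmu.to_numpy()[assignment.bmu.index.isin(gene_set.genes)],
        minlength=k)
    pvals = np.full(k, np.nan)
    for i in range(k):
        if hits[i] > 0:
            pvals[i] = hg_overrepresentation(n, int(assignment.sizes[i]), n_set,
                                             int(hits[i]), inclusive)
    return pvals


def spot_enrichment(
    spot: Spot,
    collection: list[GeneSet],
    scores: pd.Series,
    n_universe: int,
    universe: list,
    params: GSZParams | None = None,
    permutation: bool = True,
    inclusive: bool = False,
) -> list[EnrichmentResult]:
    """HG overrepresentation and sample-specific GSZ for a spot gene list.

    ``scores`` is the per-gene score of one sample restricted to the spot gene
    list.  Results are ranked by GSZ magnitude (descending), ties by HG p.
    """
    params = params or GSZParams()
    if not spot.genes:
        raise ValueError(f"spot {spot.label!r} has no genes")
    spot_scores = scores.loc[spot.genes]
    rng = np.random.default_rng(params.seed)
    results = []
    for gs in collection:
        n_pos = len(gs.genes.intersection(spot.genes))
        hg_p = hg_overrepresentation(n_universe, len(spot.genes), len(gs), n_pos,
                                     inclusive)
        z = gsz(spot_scores, gs, n_universe, params)
        perm_p = (gsz_permutation_p(z, spot_scores, len(gs), universe, params, rng)
                  if permutation else None)
        results.append(EnrichmentResult(set_name=gs.name, context=spot.source or spot.label,
                                        hg_p=hg_p, gsz=z, perm_p=perm_p, n_positive=n_pos))
    results.sort(key=lambda r: (-abs(r.gsz), r.hg_p, r.set_name))
    for i, r in enumerate(results, start=1):
        r.rank = i
    return results


def gene_set_profile(gene_set: GeneSet, scores: pd.DataFrame,
                     params: GSZParams | None = None,
                     fdr_threshold: float = 0.2) -> pd.DataFrame:
    """Per-sample overexpression Z of a set on the full list, with a
    permutation-based significance line.

    ``scores`` is genes x samples (typically the centered log expression).
    The threshold column holds the |Z| above which the permutation-null
    exceedance rate across the profile drops below ``fdr_threshold``.
    """
    params = params or GSZParams()
    zs = {}
    for m in scores.columns:
        zs[m] = gsz_full_list(scores[m], gene_set)
    prof = pd.Series(zs, name="GSZ")
    # permutation null over samples x random size-matched sets
    rng = np.random.default_rng(params.seed)
    universe = np.asarray(scores.index, dtype=object)
    size = len(gene_set.genes.intersection(scores.index))
    b = max(params.n_permutations // len(scores.columns), 20)
    null = []
    for m in scores.columns:
        for _ in range(b):
            draw = rng.choice(universe, size=size, replace=False)
            null.append(gsz_full_list(scores[m], GeneSet("null", frozenset(draw))))
    null = np.abs(np.asarray(null))
    thresh = float(np.quantile(null, 1.0 - fdr_threshold))
    out = prof.to_frame()
    out["threshold"] = thresh
    return out


def top_three_heatmap(
    results: dict[tuple[str, str], list[EnrichmentResult]],
    samples: list[str],
    top_n: int = 3,
    use: str = "perm_p",
) -> pd.DataFrame:
    """Aggregate per-(sample, spot) top gene sets into a clustered -log10 p matrix.

    Takes the ``top_n`` sets of every context list, deduplicates the union and
    fills a sets x samples matrix of -log10 p (permutation p by default, HG p
    via ``use="hg_p"``); rows are ordered by average-linkage hierarchical
    clustering on Euclidean distance.  Deterministic given fixed input.
    """
    chosen: list[str] = []
    for (_sample, _spot), res in sorted(results.items()):
        for r in res[:top_n]:
            if r.set_name not in chosen:
                chosen.append(r.set_name)
    if not chosen:
        warnings.warn("no enriched gene sets anywhere; empty heatmap", stacklevel=2)
        return pd.DataFrame(columns=samples)
    mat = pd.DataFrame(0.0, index=chosen, columns=samples)
    for (sample, _spot), res in results.items():
        for r in res:
            if r.set_name in mat.index:
                p = getattr(r, use)
                if p is not None:
                    val = -np.log10(max(p, np.finfo(float).tiny))
                    mat.loc[r.set_name, sample] = max(mat.loc[r.set_name, sample], val)
    if len(mat) > 2:
        link = hierarchy.linkage(mat.to_numpy(), method="average", metric="euclidean")
        order = hierarchy.leaves_list(link)
        mat = mat.iloc[order]
    return mat
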