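"""Seeded synthetic expression data with planted co-expression modules.

The generator emulates the structure of a replicated microarray-style
experiment on the log10 scale: a baseline log expression per gene drawn from
Normal(2.5, 0.7) (roughly three decades of dynamic range), planted modules of
genes shifted upward by a fixed effect in their active sample group,
replicate noise whose SD inflates at low expression
(sd = sigma0 + slope * max(0, e0 - e)), and a binary present call set by a
detection floor on the replicate-averaged log expression.  Everything is
fully determined by the seed.

What it deliberately does not model: probe-level effects, batch effects,
inter-gene correlation outside the planted modules, and heavy-tailed
outliers.  Tests passing on this generator therefore demonstrate method
correctness under block-structured signal with expression-dependent Gaussian
noise, not robustness to those artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genesets import GeneSet, write_gmt

__all__ = ["SyntheticTruth", "generate", "matched_gmt"]


@dataclass
class SyntheticTruth:
    """Planted structure of a synthetic data set."""

    n_modules: int = 3
    module_size: int = 100
    n_groups: int = 4
    effect: float = 1.0  # log10 units added in the active group
    baseline_mean: float = 2.5
    baseline_sd: float = 0.7
    noise_sd0: float = 0.05  # log10 replicate SD at high expression
    noise_slope: float = 0.2  # SD inflation per log10 below the knee
    noise_knee: float = 2.0  # expression level where inflation starts
    n_replicates: int = 3
    detection_floor: float = 1.5
    seed: int = 0
    modules: dict[str, list[str]] = field(default_factory=dict)  # filled by generate
    module_group: dict[str, int] = field(default_factory=dict)


def generate(
    truth: SyntheticTruth, n_genes: int, n_conditions: int
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, SyntheticTruth]:
    """Generate a replicated linear-scale expression matrix with planted modules.

    Returns ``(raw, conditions, present_calls, truth)``:
    ``raw`` is genes x (conditions * replicates) positive linear expression,
    ``conditions`` maps sample columns to condition ids, ``present_calls`` is
    the genes x conditions 0/1 detection matrix, and ``truth`` is the input
    with the realized module memberships filled in.

    Conditions are split evenly into ``truth.n_groups`` sample groups; module
    i is active (shifted by ``truth.effect``) in group i mod n_groups.
    """
    total_module = truth.n_modules * truth.module_size
    if n_genes < total_module:
        raise ValueError(f"need at least {total_module} genes for the planted modules")
    if n_conditions < truth.n_groups:
        raise ValueError("need at least one condition per sample group")
    rng = np.random.default_rng(truth.seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    conds = [f"cond{j:02d}" for j in range(n_conditions)]
    group_of_cond = np.arange(n_conditions) % truth.n_groups

    base = rng.normal(truth.baseline_mean, truth.baseline_sd, size=n_genes)
    signal = np.tile(base[:, None], (1, n_conditions))

    truth.modules = {}
    truth.module_group = {}
    pool = rng.permutation(n_genes)[:total_module]
    for i in range(truth.n_modules):
        name = f"module{i + 1}"
        members = pool[i * truth.module_size : (i + 1) * truth.module_size]
        truth.modules[name] = [genes[j] for j in sorted(members)]
        g = i % truth.n_groups
        truth.module_group[name] = g
        active = group_of_cond == g
        signal[np.ix_(members, active)] += truth.effect

    sd = truth.noise_sd0 + truth.noise_slope * np.maximum(0.0, truth.noise_knee - signal)
    cols, data, cond_map = [], [], {}
    for j, c in enumerate(conds):
        for r in range(truth.n_replicates):
            col = f"{c}_r{r + 1}"
            cols.append(col)
            cond_map[col] = c
            data.append(signal[:, j] + rng.normal(0.0, sd[:, j], size=n_genes))
    loge = np.column_stack(data)
    raw = pd.DataFrame(10.0 ** loge, index=genes, columns=cols)
    conditions = pd.Series(cond_map, name="condition")

    # present call from the replicate-averaged log expression per condition
    mean_e = np.column_stack([
        loge[:, [i for i, col in enumerate(cols) if cond_map[col] == c]].mean(axis=1)
        for c in conds
    ])
    pc = pd.DataFrame((mean_e > truth.detection_floor).astype(int), index=genes,
                      columns=conds)
    return raw, conditions, pc, truth


def matched_gmt(truth: SyntheticTruth, universe: list, n_decoys: int = 5,
                path=None) -> list[GeneSet]:
    """One true set per planted module plus size-matched random decoy sets.

    Decoys are drawn uniformly from the universe (disjointness between decoys
    is not enforced).  Written to ``path`` as GMT when given.
    """
    rng = np.random.default_rng(truth.seed + 1)
    universe = np.asarray(universe, dtype=object)
    sets: list[GeneSet] = []
    for name, members in truth.modules.items():
        sets.append(GeneSet(name=name, genes=frozenset(members), category="planted",
                            description="planted module"))
        for d in range(n_decoys):
            draw = rng.choice(universe, size=len(members), replace=False)
            sets.append(GeneSet(name=f"{name}_decoy{d + 1}", genes=frozenset(draw),
                                category="decoy", description="size-matched random set"))
    if path is not None:
        write_gmt(sets, path)
    return sets
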