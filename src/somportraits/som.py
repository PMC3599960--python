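"""Self-organizing map core: linear initialization, training, gene mapping.

The map is a rectangular grid of K = K_x * K_y metagenes, each a weight vector
of length M (one entry per condition).  Initialization is deterministic along
the two leading eigenvectors of the sample-space covariance of the gene
profiles; training is the classical Kohonen online rule with a Gaussian
neighborhood whose radius decays exponentially and a linearly decaying
learning rate.  Given a fixed seed the trained map is bit-reproducible.
Tiles use 1-based coordinates (x, y); the linear index is row-major,
k = (y-1)*K_x + (x-1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SOMGrid",
    "TrainingSchedule",
    "GeneAssignment",
    "linear_initialize",
    "best_matching_unit",
    "train",
    "map_genes",
    "metagene_expression_state",
    "save_model",
    "load_model",
]


@dataclass
class SOMGrid:
    """Rectangular metagene grid: ``weights`` has shape (K_x*K_y, M)."""

    nx: int
    ny: int
    weights: np.ndarray
    samples: list[str]

    @property
    def k(self) -> int:
        return self.nx * self.ny

    def coords(self) -> np.ndarray:
        """(K, 2) array of 1-based (x, y) tile coordinates, row-major order."""
        ys, xs = np.divmod(np.arange(self.k), self.nx)
        return np.column_stack([xs + 1, ys + 1])

    def to_field(self, values: np.ndarray) -> np.ndarray:
        """Reshape a K-vector to a (ny, nx) field."""
        return np.asarray(values).reshape(self.ny, self.nx)


@dataclass
class TrainingSchedule:
    """Online-training schedule.

    ``n_presentations`` counts individual gene presentations (not epochs).
    The learning rate decays linearly from ``rate_max`` to ``rate_min``; the
    Gaussian neighborhood radius decays exponentially from ``radius_start``
    (default: half the grid width) to ``radius_end`` over the budget.  Genes
    are presented in cyclic sweeps over a seeded shuffled order so every gene
    receives an equal number of presentations (up to one).
    """

    n_presentations: int = 250_000
    rate_max: float = 0.05
    rate_min: float = 0.01
    radius_start: float | None = None
    radius_end: float = 0.5
    seed: int = 42

    def validate(self) -> None:
        if self.n_presentations < 1:
            raise ValueError("n_presentations must be >= 1")
        if not (0.0 < self.rate_max <= 1.0):
            raise ValueError("rate_max must be in (0, 1]")
        if self.rate_min < 0 or self.rate_min > self.rate_max:
            raise ValueError("need 0 <= rate_min <= rate_max")
        if self.radius_end <= 0:
            raise ValueError("radius_end must be > 0")


@dataclass
class GeneAssignment:
    """Gene -> best-matching-metagene assignment and the induced miniclusters."""

    bmu: pd.Series  # gene id -> metagene linear index
    clusters: list[list[str]] = field(repr=False)  # per metagene, member gene ids
    sizes: np.ndarray = field(repr=False)  # n_k per metagene

    @property
    def n_genes(self) -> int:
        return len(self.bmu)


def _leading_eigenvectors(delta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cov = np.cov(delta, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    if evals[order[1]] <= 1e-12 * max(evals[order[0]], 1.0):
        raise ValueError(
            "gene-profile covariance has rank < 2; need more samples or jittered data"
        )
    v1, v2 = evecs[:, order[0]], evecs[:, order[1]]
    # reproducible sign: largest-magnitude component positive
    for v in (v1, v2):
        i = np.argmax(np.abs(v))
        if v[i] < 0:
            v *= -1.0
    return v1, v2


def linear_initialize(delta: pd.DataFrame, dims: tuple[int, int] = (60, 60)) -> SOMGrid:
    """Deterministic linear initialization along the two leading eigenvectors.

    metagene(x, y) = c_x*v1 + c_y*v2 with c_x = 2*(x-1)/(K_x-1) - 1 (likewise
    c_y), so the coefficients span [-1, +1] across the grid and repeated runs
    on the same input give identical grids.
    """
    nx, ny = dims
    if delta.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    v1, v2 = _leading_eigenvectors(delta.to_numpy(dtype=float))
    cx = 2.0 * np.arange(nx) / (nx - 1) - 1.0 if nx > 1 else np.zeros(1)
    cy = 2.0 * np.arange(ny) / (ny - 1) - 1.0 if ny > 1 else np.zeros(1)
    weights = cx[None, :, None] * v1 + cy[:, None, None] * v2  # (ny, nx, M)
    return SOMGrid(nx=nx, ny=ny, weights=weights.reshape(nx * ny, -1),
                   samples=list(delta.columns))


def best_matching_unit(profile: np.ndarray, grid: SOMGrid) -> int:
    """Index of the Euclidean-closest metagene; ties -> lowest linear index."""
    d2 = np.square(grid.weights - np.asarray(profile, dtype=float)).sum(axis=1)
    return int(np.argmin(d2))


def train(delta: pd.DataFrame, grid: SOMGrid, schedule: TrainingSchedule) -> SOMGrid:
    """Kohonen online training; returns a new grid, the input is untouched.

    Each presentation picks the next gene in a seeded shuffled cyclic order,
    finds its best matching unit and moves the BMU and its grid neighbors
    toward the gene profile by ``rate * exp(-d^2 / 2 sigma_i^2)``.
    """
    schedule.validate()
    data = np.ascontiguousarray(delta.to_numpy(dtype=float))
    n, m = data.shape
    if m != grid.weights.shape[1]:
        raise ValueError("sample dimension of data and grid differ")
    w = grid.weights.copy()
    coords = grid.coords().astype(float)
    t_total = schedule.n_presentations
    r0 = schedule.radius_start if schedule.radius_start is not None else grid.nx / 2.0
    r1 = schedule.radius_end
    rng = np.random.default_rng(schedule.seed)
    order = rng.permutation(n)
    pos = 0
    log_ratio = np.log(r1 / r0) if r0 > 0 else 0.0
    for i in range(t_total):
        g = data[order[pos]]
        pos += 1
        if pos == n:
            pos = 0
            order = rng.permutation(n)
        frac = i / max(t_total - 1, 1)
        rate = schedule.rate_max + frac * (schedule.rate_min - schedule.rate_max)
        sigma = r0 * np.exp(frac * log_ratio)
        d2 = np.square(w - g).sum(axis=1)
        bmu = int(np.argmin(d2))
        gd2 = np.square(coords - coords[bmu]).sum(axis=1)
        # tiles with a negligible neighborhood factor are skipped
        cutoff = 2.0 * sigma * sigma * 16.0  # exp(-16) ~ 1e-7
        near = gd2 <= cutoff
        h = np.exp(-gd2[near] / (2.0 * sigma * sigma))
        w[near] += rate * h[:, None] * (g - w[near])
        if not np.all(np.isfinite(w[near])):
            raise FloatingPointError(
                f"non-finite SOM weight at presentation {i} (gene {delta.index[order[pos - 1]]!r})"
            )
    return SOMGrid(nx=grid.nx, ny=grid.ny, weights=w, samples=list(grid.samples))


def map_genes(delta: pd.DataFrame, grid: SOMGrid) -> GeneAssignment:
    """Assign every gene to its best matching metagene (final mapping step)."""
    data = delta.to_numpy(dtype=float)
    w = grid.weights
    # chunked distance computation keeps memory bounded for large N*K
    bmu = np.empty(len(data), dtype=int)
    w_sq = np.square(w).sum(axis=1)
    step = max(1, 2_000_000 // max(grid.k, 1))
    for start in range(0, len(data), step):
        block = data[start : start + step]
        d2 = w_sq[None, :] - 2.0 * block @ w.T
        bmu[start : start + step] = np.argmin(d2, axis=1)
    genes = list(delta.index)
    clusters: list[list[str]] = [[] for _ in range(grid.k)]
    for gene, k in zip(genes, bmu):
        clusters[k].append(gene)
    sizes = np.bincount(bmu, minlength=grid.k)
    return GeneAssignment(bmu=pd.Series(bmu, index=delta.index), clusters=clusters, sizes=sizes)


def metagene_expression_state(grid: SOMGrid, sample) -> np.ndarray:
    """Column of the metagene matrix for one sample (its "expression state")."""
    if isinstance(sample, str):
        if sample not in grid.samples:
            raise KeyError(f"unknown sample {sample!r}")
        j = grid.samples.index(sample)
    else:
        j = int(sample)
        if not 0 <= j < len(grid.samples):
            raise IndexError(f"sample index {j} out of range")
    return grid.weights[:, j].copy()


def save_model(path, grid: SOMGrid, assignment: GeneAssignment | None = None,
               schedule: TrainingSchedule | None = None) -> None:
    """Serialize a trained map as a directory of TSV + JSON files."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(grid.weights, columns=grid.samples).to_csv(
        path / "weights.tsv", sep="\t", index_label="metagene", float_format="%.12g")
    meta = {"nx": grid.nx, "ny": grid.ny, "samples": grid.samples}
    if schedule is not None:
        meta["schedule"] = asdict(schedule)
    (path / "model.json").write_text(json.dumps(meta, indent=1))
    if assignment is not None:
        assignment.bmu.rename("metagene").to_csv(path / "assignment.tsv", sep="\t",
                                                 index_label="gene")


def load_model(path) -> tuple[SOMGrid, GeneAssignment | None]:
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    wdf = pd.read_csv(path / "weights.tsv", sep="\t", index_col=0)
    grid = SOMGrid(nx=meta["nx"], ny=meta["ny"], weights=wdf.to_numpy(float),
                   samples=meta["samples"])
    assignment = None
    if (path / "assignment.tsv").exists():
        bmu = pd.read_csv(path / "assignment.tsv", sep="\t", index_col=0)["metagene"]
        clusters: list[list[str]] = [[] for _ in range(grid.k)]
        for gene, k in bmu.items():
            clusters[int(k)].append(gene)
        assignment = GeneAssignment(bmu=bmu, clusters=clusters,
                                    sizes=np.bincount(bmu, minlength=grid.k))
    return grid, assignment
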