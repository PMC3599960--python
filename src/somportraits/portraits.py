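"""Portrait rendering: per-sample mosaics, summary maps, rank and population maps.

Every map is a scalar field over the K grid tiles, rendered with a two-segment
linear color scale anchored at the field's own minimum (blue), arithmetic mean
(green) and maximum (maroon).  Empty metagenes (n_k = 0) are masked and drawn
white.  Because the scale is anchored at min/mean/max of the field itself,
rendering is equivariant under affine transforms of the field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image

from .som import GeneAssignment, SOMGrid

__all__ = [
    "MosaicImage",
    "SummaryMaps",
    "render_mosaic",
    "save_png",
    "summary_maps",
    "rank_map",
    "population_map",
]

BLUE = np.array([0, 0, 255], dtype=float)
GREEN = np.array([0, 128, 0], dtype=float)
MAROON = np.array([128, 0, 0], dtype=float)
WHITE = np.array([255, 255, 255], dtype=float)


@dataclass
class MosaicImage:
    """Rendered K_y x K_x mosaic with its underlying scalar field and mask."""

    rgb: np.ndarray  # (ny, nx, 3) uint8
    field: np.ndarray  # (ny, nx) float, NaN where masked
    mask: np.ndarray  # (ny, nx) bool, True = empty tile


@dataclass
class SummaryMaps:
    """Per-metagene extrema over samples: over = max, under = min."""

    over: np.ndarray
    under: np.ndarray


def _colorize(field: np.ndarray, mask: np.ndarray) -> np.ndarray:
    vals = field[~mask]
    lo, hi, mid = vals.min(), vals.max(), vals.mean()
    rgb = np.empty(field.shape + (3,), dtype=float)
    rgb[mask] = WHITE
    v = field[~mask]
    out = np.empty((v.size, 3))
    tol = 1e-12 * max(1.0, abs(hi), abs(lo))
    if hi - lo <= tol:  # constant field: everything sits at the mean -> green
        out[:] = GREEN
    else:
        lower = v <= mid
        if mid - lo > tol:
            f = np.clip((v[lower] - lo) / (mid - lo), 0.0, 1.0)[:, None]
            out[lower] = BLUE + f * (GREEN - BLUE)
        else:
            out[lower] = GREEN
        if hi - mid > tol:
            f = np.clip((v[~lower] - mid) / (hi - mid), 0.0, 1.0)[:, None]
            out[~lower] = GREEN + f * (MAROON - GREEN)
        else:
            out[~lower] = GREEN
    rgb[~mask] = out
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def render_mosaic(field, dims: tuple[int, int], mask=None) -> MosaicImage:
    """Render a K-vector as a color mosaic (blue -> green -> maroon).

    ``dims`` is (K_x, K_y); the field is laid out row-major.  ``mask`` marks
    empty tiles (rendered white).
    """
    nx, ny = dims
    field = np.asarray(field, dtype=float).reshape(ny, nx)
    if mask is None:
        mask = ~np.isfinite(field)
    else:
        mask = np.asarray(mask, dtype=bool).reshape(ny, nx) | ~np.isfinite(field)
    if mask.all():
        raise ValueError("all tiles masked; nothing to render")
    shown = np.where(mask, np.nan, field)
    return MosaicImage(rgb=_colorize(np.nan_to_num(field), mask), field=shown, mask=mask)


def save_png(img: MosaicImage, path, scale: int = 10) -> None:
    """Write the mosaic as a PNG, each tile enlarged to ``scale`` x ``scale`` px."""
    im = Image.fromarray(img.rgb, mode="RGB")
    im = im.resize((img.rgb.shape[1] * scale, img.rgb.shape[0] * scale), Image.NEAREST)
    im.save(path)


def save_field_tsv(img: MosaicImage, path) -> None:
    pd.DataFrame(img.field).to_csv(path, sep="\t", float_format="%.10g")


def summary_maps(grid: SOMGrid) -> SummaryMaps:
    """Per-metagene max/min over all samples (over/underexpression summaries)."""
    return SummaryMaps(over=grid.weights.max(axis=1), under=grid.weights.min(axis=1))


def rank_map(assignment: GeneAssignment, global_ranks: pd.Series) -> np.ndarray:
    """Mean rank of the member genes per metagene; empty tiles are NaN.

    ``global_ranks`` must rank every analyzed gene (1..N) for one sample and
    one score.
    """
    missing = assignment.bmu.index.difference(global_ranks.index)
    if len(missing):
        raise ValueError(f"ranked list does not cover all genes ({len(missing)} missing)")
    k = len(assignment.clusters)
    sums = np.bincount(assignment.bmu.to_numpy(),
                       weights=global_ranks.loc[assignment.bmu.index].to_numpy(),
                       minlength=k)
    with np.errstate(invalid="ignore"):
        return sums / np.where(assignment.sizes > 0, assignment.sizes, np.nan)


def population_map(members, assignment: GeneAssignment) -> np.ndarray:
    """Count of gene-set members assigned to each metagene."""
    members = set(members)
    hit = assignment.bmu.index.isin(members)
    if not hit.any():
        warnings.warn("gene set does not intersect the analyzed genes", stacklevel=2)
    return np.bincount(assignment.bmu.to_numpy()[hit], minlength=len(assignment.clusters)).astype(float)
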