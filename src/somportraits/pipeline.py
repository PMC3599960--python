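"""End-to-end pipeline: preprocess -> SOM -> portraits -> spots -> scores ->
list comparison -> gene-set enrichment -> special sets -> report directory.

The single entry point is :func:`run_pipeline`, driven by a config dict (or
YAML file).  All outputs are plain TSV/PNG/JSON; reruns with the same config
and seed are bit-identical on the TSV side.  A zoom-in run is the identical
pipeline on a sample subset (``samples`` config key) with an unchanged grid.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, genesets, listcomp, portraits, preprocess, som, special_sets, spots

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "scale": "linear",  # linear | log10
    "quantile_normalize": True,
    "grid": [20, 20],
    "iterations": 20000,
    "rate_max": 0.05,
    "rate_min": 0.01,
    "radius_end": 0.5,
    "seed": 42,
    "spot_quantile": 0.98,
    "lambda_shr": 0.5,
    "lpe_window": 200,
    "hg_tail": "strict",  # strict | inclusive
    "gsz_n_list_min": 10,
    "gsz_n_set_min": 10,
    "permutations": 1000,
    "run_permutations": True,
    "cat_rmax": 100,
    "rc_window": 20,
    "special_fraction": 0.10,
    "samples": None,  # optional condition subset for zoom-in
    "png_scale": 10,
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(user)
    return cfg


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)


def _save_map(field, grid, mask, out_png, out_tsv, png_scale) -> None:
    img = portraits.render_mosaic(field, (grid.nx, grid.ny), mask)
    portraits.save_png(img, out_png, scale=png_scale)
    portraits.save_field_tsv(img, out_tsv)


def run_pipeline(
    raw: pd.DataFrame,
    conditions: pd.Series,
    outdir,
    config: dict | None = None,
    gene_sets: list | None = None,
    present_calls: pd.DataFrame | None = None,
) -> dict:
    """Run the full analysis and write the report directory.

    Returns a result dict with the in-memory objects (delta matrix, grid,
    assignment, spots, score tables, fdr estimates, enrichment results) for
    further use from Python.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    t0 = time.time()

    def tick(stage):
        timings[stage] = round(time.time() - t0, 3)

    if cfg["samples"]:  # zoom-in: restrict to a condition subset
        keep = [s for s in raw.columns if conditions[s] in set(cfg["samples"])]
        raw = raw[keep]
        conditions = conditions.loc[keep]

    # ---- preprocess -------------------------------------------------------
    delta, log_expr = preprocess.preprocess(
        raw, conditions, scale=cfg["scale"], normalize=cfg["quantile_normalize"])
    _write_tsv(delta, out / "delta_expression.tsv", index_label="gene")
    tick("preprocess")

    # ---- SOM --------------------------------------------------------------
    nx, ny = cfg["grid"]
    grid = som.linear_initialize(delta, (nx, ny))
    schedule = som.TrainingSchedule(
        n_presentations=cfg["iterations"], rate_max=cfg["rate_max"],
        rate_min=cfg["rate_min"], radius_end=cfg["radius_end"], seed=cfg["seed"])
    grid = som.train(delta, grid, schedule)
    assignment = som.map_genes(delta, grid)
    som.save_model(out / "model", grid, assignment, schedule)
    tick("som")

    # ---- portraits --------------------------------------------------------
    pdir = out / "portraits"
    pdir.mkdir(exist_ok=True)
    empty_mask = assignment.sizes == 0
    for m in grid.samples:
        state = som.metagene_expression_state(grid, m)
        _save_map(state, grid, empty_mask, pdir / f"portrait_{m}.png",
                  pdir / f"portrait_{m}.tsv", cfg["png_scale"])
    summaries = portraits.summary_maps(grid)
    _save_map(summaries.over, grid, empty_mask, out / "summary_over.png",
              out / "summary_over.tsv", cfg["png_scale"])
    _save_map(summaries.under, grid, empty_mask, out / "summary_under.png",
              out / "summary_under.tsv", cfg["png_scale"])
    tick("portraits")

    # ---- spots ------------------------------------------------------------
    q = cfg["spot_quantile"]
    over_spots, under_spots = spots.summary_spots(
        summaries, (grid.nx, grid.ny), q, assignment)
    sample_spots = {m: spots.detect_spots(som.metagene_expression_state(grid, m),
                                          (grid.nx, grid.ny), "over", q, assignment, m)
                    for m in grid.samples}
    sdir = out / "spots"
    sdir.mkdir(exist_ok=True)
    rows = []
    for spot in over_spots + under_spots + [s for ss in sample_spots.values() for s in ss]:
        x, y = spot.peak % grid.nx + 1, spot.peak // grid.nx + 1
        rows.append({"label": spot.label, "polarity": spot.polarity,
                     "source": spot.source, "n_tiles": spot.n_tiles,
                     "n_genes": spot.n_genes, "peak_x": x, "peak_y": y,
                     "peak_value": spot.peak_value})
        if spot.source == "summary":
            pd.Series(spot.genes, name="gene").to_csv(
                sdir / f"genes_{spot.polarity}_{spot.label}.tsv", sep="\t", index=False)
    _write_tsv(pd.DataFrame(rows), out / "spot_report.tsv", index=False)
    tick("spots")

    # ---- differential expression -----------------------------------------
    scores = diffexpr.score_table(
        delta, log_expr.values, log_expr.sigma, log_expr.n_replicates,
        lam=cfg["lambda_shr"], lpe_window=cfg["lpe_window"])
    for key in ("logFC", "WAD", "t", "p"):
        _write_tsv(scores[key], out / f"score_{key}.tsv", index_label="gene")
    fdr_by_sample = {}
    fdr_rows = []
    for m in delta.columns:
        est = diffexpr.estimate_fdr(scores["p"][m].to_numpy())
        fdr_by_sample[m] = est
        fdr_rows.append({"sample": m, "eta0": est.eta0, "pct_DE": est.pct_de,
                         "fdr_at_1": float(est.fdr(1.0)), "Fdr_at_1": float(est.Fdr(1.0))})
    _write_tsv(pd.DataFrame(fdr_rows), out / "fdr_summary.tsv", index=False)
    grid_p = np.linspace(0.0, 1.0, 101)
    curves = {m: est.fdr(grid_p) for m, est in fdr_by_sample.items()}
    curves_df = pd.DataFrame(curves, index=grid_p)
    _write_tsv(curves_df, out / "fdr_curves.tsv", index_label="p")
    tick("diffexpr")

    # ---- rank maps & ranked-list comparison ------------------------------
    ranked: dict[str, dict[str, list]] = {}
    for m in delta.columns:
        ranked[m] = {}
        for score_name in ("logFC", "WAD", "t"):
            r = diffexpr.rank_genes(scores[score_name][m])
            ranked[m][score_name] = list(r.index)
    m0 = list(delta.columns)[0]
    rmap = diffexpr.rank_genes(scores["t"][m0])
    rank_field = portraits.rank_map(assignment, rmap)
    _save_map(rank_field, grid, empty_mask, out / f"rankmap_t_{m0}.png",
              out / f"rankmap_t_{m0}.tsv", cfg["png_scale"])
    cat_rows = []
    r_max = min(cfg["cat_rmax"], len(delta))
    for a, b in (("logFC", "WAD"), ("logFC", "t"), ("WAD", "t")):
        curve = listcomp.cat(ranked[m0][a], ranked[m0][b], r_max)
        dp = listcomp.delta_p_cat(ranked[m0][a], ranked[m0]["t"], scores["p"][m0], r_max)
        for i in range(r_max):
            cat_rows.append({"pair": f"{a}_vs_{b}", "r": i + 1,
                             "CAT": curve.cat[i], "null": curve.null[i],
                             "delta_p_CAT": dp[i]})
    _write_tsv(pd.DataFrame(cat_rows), out / "cat_diagnostics.tsv", index=False)
    tick("listcomp")

    # ---- gene sets --------------------------------------------------------
    result_sets = {}
    if gene_sets:
        universe = list(delta.index)
        params = genesets.GSZParams(
            n_list_min=cfg["gsz_n_list_min"], n_set_min=cfg["gsz_n_set_min"],
            n_permutations=cfg["permutations"], seed=cfg["seed"])
        inclusive = cfg["hg_tail"] == "inclusive"
        enr: dict[tuple[str, str], list] = {}
        for m in delta.columns:
            for spot in sample_spots[m]:
                enr[(m, spot.label)] = genesets.spot_enrichment(
                    spot, gene_sets, scores["t"][m], len(universe), universe,
                    params, permutation=cfg["run_permutations"], inclusive=inclusive)
        enr_rows = [{"sample": m, "spot": lab, "set": r.set_name, "rank": r.rank,
                     "HG_p": r.hg_p, "GSZ": r.gsz, "perm_p": r.perm_p,
                     "n_positive": r.n_positive}
                    for (m, lab), res in sorted(enr.items()) for r in res]
        _write_tsv(pd.DataFrame(enr_rows), out / "spot_enrichment.tsv", index=False)
        heat = genesets.top_three_heatmap(
            enr, list(delta.columns),
            use="perm_p" if cfg["run_permutations"] else "hg_p")
        _write_tsv(heat, out / "top_three_heatmap.tsv", index_label="set")
        if len(heat):
            _heatmap_png(heat, out / "top_three_heatmap.png")
        # overrepresentation map + GSZ profile of the overall top set
        top = min(gene_sets, key=lambda s: genesets.hg_overrepresentation(
            len(universe), len(over_spots[0].genes) if over_spots else len(universe),
            len(s), len(s.genes.intersection(over_spots[0].genes)) if over_spots else len(s),
            inclusive))
        pmap = genesets.metagene_overrepresentation_map(top, assignment, inclusive)
        with np.errstate(divide="ignore"):
            field = -np.log10(np.maximum(pmap, np.finfo(float).tiny))
        _save_map(field, grid, ~np.isfinite(pmap), out / f"overrep_{top.name}.png",
                  out / f"overrep_{top.name}.tsv", cfg["png_scale"])
        prof = genesets.gene_set_profile(top, delta, params)
        _write_tsv(prof, out / f"gsz_profile_{top.name}.tsv", index_label="sample")
        result_sets = {"enrichment": enr, "heatmap": heat, "top_set": top}
    tick("genesets")

    # ---- special sets -----------------------------------------------------
    specials = []
    for crit in ("high_expression", "housekeeper_mean"):
        specials.append(special_sets.select_special_set(
            crit, delta=delta, e=log_expr.values, fraction=cfg["special_fraction"]))
    if present_calls is not None:
        pcs = present_calls.loc[delta.index, delta.columns]
        for crit in ("absent", "housekeeper_present"):
            s = special_sets.select_special_set(crit, present_calls=pcs)
            if len(s):
                specials.append(s)
    specials = [s for s in specials if len(s)]
    if specials:
        genesets.write_gmt(specials, out / "special_sets.gmt")
        for s in specials:
            pop = portraits.population_map(s.genes, assignment)
            _save_map(pop, grid, empty_mask, out / f"population_{s.name}.png",
                      out / f"population_{s.name}.tsv", cfg["png_scale"])
    tick("special_sets")

    manifest = {"config": {k: v for k, v in cfg.items()},
                "n_genes": int(delta.shape[0]), "n_conditions": int(delta.shape[1]),
                "timings_s": timings}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    logger.info("pipeline finished: %s", timings)
    return {"delta": delta, "log_expr": log_expr, "grid": grid,
            "assignment": assignment, "summaries": summaries,
            "over_spots": over_spots, "under_spots": under_spots,
            "sample_spots": sample_spots, "scores": scores,
            "fdr": fdr_by_sample, "special_sets": specials, **result_sets}


def _heatmap_png(mat: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list("wyr", ["white", "yellow", "red"])
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * mat.shape[1] + 2),
                                    max(3, 0.25 * mat.shape[0] + 1)))
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap=cmap)
    ax.set_xticks(range(mat.shape[1]), labels=mat.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(mat.shape[0]), labels=mat.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
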