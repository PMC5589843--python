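"""Stage orchestration: synth -> preprocess -> correlate -> debias ->
crosslake -> validate, with every intermediate written as CSV so each number
in the final reports is traceable to a file.

Each stage function reads its inputs from the artifact directory and writes
its outputs there, so the CLI verbs and the numbered analysis scripts are
thin wrappers.  Re-running with an identical configuration reproduces
byte-identical outputs: all randomness is seeded from the config and no
timestamps enter the artifacts (logging goes to the standard logger, not
into the directory).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import brt, crosslake, debias, pixelcorr, preprocess, synth, validate
from .exceptions import InsufficientDataError
from .io import PipelineConfig, config_hash, read_observations, write_observations

__all__ = [
    "run_pipeline",
    "stage_simulate",
    "stage_preprocess",
    "stage_correlate",
    "stage_debias",
    "stage_crosslake",
    "stage_validate",
]

logger = logging.getLogger(__name__)


def _out(cfg: PipelineConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _lr_grid(cfg: PipelineConfig):
    return tuple(r for r in brt.LEARNING_RATE_GRID if r >= cfg.learning_rate_floor)


def _brt_spec(cfg: PipelineConfig, depth: int) -> brt.BRTFitSpec:
    return brt.BRTFitSpec(
        interaction_depth=depth,
        min_trees=cfg.min_trees,
        max_trees=cfg.max_trees,
        bag_fraction=cfg.bag_fraction,
        cv_folds=cfg.cv_folds,
        patience=cfg.patience,
    )


def stage_simulate(cfg: PipelineConfig) -> None:
    """Generate the synthetic archive: observations, truth, catalog, in-situ."""
    sb = cfg.synthetic
    if sb is None:
        raise InsufficientDataError("no synthetic block configured; provide observations_path instead")
    out = _out(cfg)
    scenarios = synth.generate_lake_catalog(
        sb.n_lakes,
        seed=cfg.seeds["synth"],
        amplification=sb.amplification,
        attr_missing_frac=sb.attr_missing_frac,
        n_pixels_lat=sb.n_pixels_lat,
        n_pixels_lon=sb.n_pixels_lon,
        years=sb.years,
        missingness=synth.MissingnessModel(
            summer_prob=sb.summer_prob, winter_prob=sb.winter_prob, shape=sb.missingness_shape
        ),
    )
    obs_parts, truth_parts = [], []
    for sc in scenarios:
        obs, truth = synth.simulate_observations(sc)
        obs_parts.append(obs)
        truth_parts.append(truth.strata.assign(true_r_lake=truth.true_r_lake))
    obs = pd.concat(obs_parts, ignore_index=True)
    write_observations(obs, out / "observations.csv")
    pd.concat(truth_parts, ignore_index=True).to_csv(out / "truth.csv", index=False)
    synth.catalog_frame(scenarios).to_csv(out / "catalog.csv", index=False)

    rng = np.random.default_rng(cfg.seeds["insitu"])
    insitu_parts = []
    for sc in scenarios[: sb.insitu_lakes]:
        grid = obs[obs["lake_id"] == sc.lake_id]
        n = min(sb.insitu_samples, len(grid))
        if n < 3:
            continue
        insitu_parts.append(
            synth.simulate_insitu_samples(
                sc,
                grid,
                error_sd_lst=sb.insitu_error_sd_lst,
                error_bias_chla=sb.insitu_error_bias_chla,
                n_samples=n,
                seed=int(rng.integers(2**31 - 1)),
                error_sd_log_chla=sb.insitu_error_sd_log_chla,
            )
        )
    if insitu_parts:
        ins = pd.concat(insitu_parts, ignore_index=True)
        ins["date"] = pd.DatetimeIndex(ins["date"]).strftime("%Y-%m-%d")
        ins.to_csv(out / "insitu.csv", index=False)
    logger.info("simulate: %d lakes, %d observations", sb.n_lakes, len(obs))


def stage_preprocess(cfg: PipelineConfig) -> None:
    """Median-filter reductions and coincident matching."""
    out = _out(cfg)
    src = out / "observations.csv" if (out / "observations.csv").exists() else cfg.observations_path
    obs = read_observations(src)
    lst = preprocess.spatial_median_subset(obs[["lake_id", "lat", "lon", "date", "lst"]], "lst", cfg.cell_size)
    chla = preprocess.spatial_median_subset(obs[["lake_id", "lat", "lon", "date", "chla"]], "chla", cfg.cell_size)
    lst = preprocess.temporal_median_subset(lst, "lst")
    chla = preprocess.temporal_median_subset(chla, "chla")
    pairs = preprocess.match_coincident(lst, chla, cfg.cell_size)
    if cfg.lake_masks_path:
        masks = pd.read_csv(cfg.lake_masks_path)
        pairs = preprocess.assign_lakes(pairs, masks)
    write_observations(pairs, out / "preprocessed.csv")
    logger.info("preprocess: %d coincident pairs", len(pairs))


def stage_correlate(cfg: PipelineConfig) -> None:
    """The field of stratum Kendall correlations."""
    out = _out(cfg)
    pairs = read_observations(out / "preprocessed.csv")
    field = pixelcorr.correlation_field_from_pairs(pairs, min_obs=cfg.min_obs)
    field.to_csv(out / "correlations.csv", index=False)
    logger.info("correlate: %d correlation records", len(field))


def stage_debias(cfg: PipelineConfig) -> None:
    """Balanced r_lake per lake with Wilcoxon tests and BH correction."""
    out = _out(cfg)
    field = pd.read_csv(out / "correlations.csv")
    summaries = debias.debias_lakes(
        field,
        seed=cfg.seeds["debias"],
        subsample_cap=cfg.subsample_cap,
        spec=debias.default_surface_spec(
            min_trees=cfg.min_trees, max_trees=cfg.max_trees,
            bag_fraction=cfg.bag_fraction, cv_folds=cfg.cv_folds, patience=cfg.patience,
        ),
        alpha=cfg.alpha,
        lr_grid=_lr_grid(cfg),
    )
    summaries.to_csv(out / "lake_summaries.csv", index=False)
    n_ok = int(summaries["r_lake"].notna().sum())
    logger.info("debias: %d lakes summarized, %d excluded", n_ok, len(summaries) - n_ok)


def stage_crosslake(cfg: PipelineConfig) -> None:
    """Cross-lake weighted BRT, relative influence, median-chl-a effect."""
    out = _out(cfg)
    summaries = pd.read_csv(out / "lake_summaries.csv")
    catalog = pd.read_csv(out / "catalog.csv") if (out / "catalog.csv").exists() else pd.read_csv(cfg.catalog_path)
    pairs = read_observations(out / "preprocessed.csv")
    # Median temperature / chl-a come from each lake's own reduced pairs.
    med = pairs.groupby("lake_id", sort=True).agg(median_temperature=("lst", "median"), median_chla=("chla", "median")).reset_index()
    catalog = catalog.drop(columns=["median_temperature", "median_chla"], errors="ignore").merge(med, on="lake_id", how="left")
    table = crosslake.assemble_table(catalog, summaries)
    table.to_csv(out / "crosslake_table.csv", index=False)
    try:
        model = crosslake.fit_crosslake(
            table, seed=cfg.seeds["crosslake"],
            spec=_brt_spec(cfg, depth=len([c for c in crosslake.CATALOG_PREDICTORS if c in table.columns])),
        )
    except InsufficientDataError as exc:
        logger.warning("crosslake: stage skipped (%s)", exc)
        (out / "crosslake_skipped.txt").write_text(f"insufficient data: {exc}\n")
        return
    infl = model.relative_influence.rename_axis("predictor").reset_index()
    infl.to_csv(out / "relative_influence.csv", index=False)
    curve = crosslake.medianchl_effect(model, table)
    curve.to_csv(out / "medianchl_effect.csv", index=False)
    brt.save_model(model, out / "crosslake_model.pkl")
    logger.info("crosslake: top influence %s", infl.iloc[infl["relative_influence"].idxmax()]["predictor"])


def stage_validate(cfg: PipelineConfig) -> None:
    """Satellite vs in-situ statistics, if an in-situ table exists."""
    out = _out(cfg)
    path = out / "insitu.csv" if (out / "insitu.csv").exists() else cfg.insitu_path
    if path is None or not Path(path).exists():
        logger.info("validate: no in-situ data; stage skipped")
        return
    ins = pd.read_csv(path, parse_dates=["date"])
    pairs = read_observations(out / "preprocessed.csv")
    matched = {
        "lst": validate.match_nearest(ins, pairs, "lst", "insitu_lst"),
        "chla": validate.match_nearest(ins, pairs, "chla", "insitu_chla"),
    }
    lake_level = {}
    med_ins = ins.groupby("lake_id")["insitu_chla"].median().rename("insitu_value")
    med_sat = pairs.groupby("lake_id")["chla"].median().rename("satellite_value")
    ml = pd.concat([med_ins, med_sat], axis=1, join="inner").reset_index()
    lake_level["median_chla"] = ml
    report = validate.validation_report(matched, lake_level)
    validate.report_frame(report).to_csv(out / "validation_report.csv", index=False)
    (out / "validation_report.txt").write_text(validate.report_text(report))
    logger.info("validate: report written")


_STAGES = [
    ("simulate", stage_simulate),
    ("preprocess", stage_preprocess),
    ("correlate", stage_correlate),
    ("debias", stage_debias),
    ("crosslake", stage_crosslake),
    ("validate", stage_validate),
]


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute every stage in order and write the run manifest.

    Halts on stage failure with the stage name in the raised error.
    """
    cfg.validate()
    out = _out(cfg)
    for name, fn in _STAGES:
        if name == "simulate" and cfg.synthetic is None:
            continue
        try:
            fn(cfg)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    from . import __version__

    manifest = {
        "config": cfg.to_dict(),
        "config_sha256": config_hash(cfg),
        "package_version": __version__,
        "stages": [name for name, _ in _STAGES if not (name == "simulate" and cfg.synthetic is None)],
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return out
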