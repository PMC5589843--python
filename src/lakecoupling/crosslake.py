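"""Cross-lake attribution: which lake attributes explain r_lake?

A single weighted boosted regression tree models r_lake across lakes using
eight predictors — elevation, latitude, surface area, perimeter, mean depth,
salinity class (fresh/saline), median temperature, and median chl-a — with
each lake weighted by the significance of its own correlation
(weight = 1 - p).  The per-predictor relative influence and the isolated
median-chl-a partial-dependence curve are the outputs of interest: under
trophic-state amplification the curve runs from negative associations in
phytoplankton-poor lakes to positive ones in phytoplankton-rich lakes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from . import brt

__all__ = [
    "CATALOG_PREDICTORS",
    "assemble_table",
    "fit_crosslake",
    "medianchl_effect",
]

logger = logging.getLogger(__name__)

CATALOG_PREDICTORS = [
    "elevation",
    "latitude",
    "surface_area",
    "perimeter",
    "mean_depth",
    "salinity_class",
    "median_temperature",
    "median_chla",
]


def assemble_table(catalog: pd.DataFrame, summaries: pd.DataFrame) -> pd.DataFrame:
    """Join lake summaries onto the catalog into the modeling table.

    One row per non-excluded lake; the response is r_lake and the
    observation weight is ``1 - wilcoxon_p`` clipped to [0, 1].  Missing
    predictor values are retained as missing (the trees route them).  Every
    summarized lake must exist in the catalog.
    """
    usable = summaries[summaries["r_lake"].notna() & summaries["wilcoxon_p"].notna()]
    missing = sorted(set(usable["lake_id"]) - set(catalog["lake_id"]))
    if missing:
        raise ValueError(f"lakes absent from catalog: {', '.join(map(str, missing))}")
    cols = ["lake_id"] + [c for c in CATALOG_PREDICTORS if c in catalog.columns]
    table = usable[["lake_id", "r_lake", "wilcoxon_p"]].merge(catalog[cols], on="lake_id", how="left")
    table["weight"] = np.clip(1.0 - table["wilcoxon_p"].to_numpy(float), 0.0, 1.0)
    return table.drop(columns=["wilcoxon_p"]).sort_values("lake_id").reset_index(drop=True)


def fit_crosslake(table: pd.DataFrame, seed: int, spec: brt.BRTFitSpec | None = None) -> brt.BRTModel:
    """Weighted boosted-tree fit of r_lake on the eight catalog predictors.

    Interaction depth equals the predictor count (the complexity rule); the
    table is canonicalized by lake_id so row order cannot change the fit.
    Tuning failure raises the insufficient-data signal for this stage.
    """
    table = table.sort_values("lake_id").reset_index(drop=True)
    predictors = [c for c in CATALOG_PREDICTORS if c in table.columns]
    model_table = table[predictors + ["r_lake"]]
    weights = table["weight"].to_numpy(float) if "weight" in table.columns else None
    if spec is None:
        spec = brt.BRTFitSpec(interaction_depth=len(predictors))
    spec = replace(spec, interaction_depth=len(predictors), weights=weights, seed=seed)
    if spec.n_trees is not None:
        return brt.fit_brt(model_table, "r_lake", spec)
    return brt.tune_learning_rate(model_table, "r_lake", spec)


def medianchl_effect(
    model: brt.BRTModel,
    table: pd.DataFrame,
    grid: np.ndarray | None = None,
    n_grid: int = 50,
) -> pd.DataFrame:
    """Isolated effect of median chl-a on r_lake (partial dependence).

    The curve is evaluated on a log-spaced grid spanning the observed
    median-chl-a range (values outside it are clipped with a warning) and is
    returned with display-transform columns matching the conventional axes:
    log10 median chl-a on x and a hyperbolic-sine transform on y.
    """
    observed = table["median_chla"].dropna().to_numpy(float)
    lo, hi = float(observed.min()), float(observed.max())
    if grid is None:
        grid = np.logspace(np.log10(lo), np.log10(hi), n_grid)
    else:
        grid = np.asarray(grid, dtype=float)
        if grid.size == 0:
            raise ValueError("median-chl-a grid is empty")
        if (grid < lo).any() or (grid > hi).any():
            warnings.warn("grid extends beyond the observed median-chl-a range; clipping", stacklevel=2)
            grid = np.clip(grid, lo, hi)
    curve = brt.partial_dependence(model, "median_chla", grid)
    curve = curve.rename(columns={"median_chla": "median_chla", "effect": "effect"})
    curve["log10_median_chla"] = np.log10(curve["median_chla"])
    curve["asinh_effect"] = np.arcsinh(curve["effect"])
    return curve
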