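"""Median-filter reductions, coincident matching, and lake assignment.

Grid conventions
----------------
Space: half-open 0.1-degree cells ``[k*0.1, (k+1)*0.1)`` anchored at integer
multiples of the cell size; the reported coordinate is the cell center.
Time: 5-day bins anchored at Jan 1 of each calendar year,
``bin = (doy - 1) // 5 + 1``; bin 73 absorbs days 361-366 so leap years do
not shift the strata.  Binning by calendar year keeps strata aligned across
years, which the interannual correlation requires.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = [
    "N_BINS",
    "BIN_DAYS",
    "doy_bin",
    "bin_mid_doy",
    "spatial_median_subset",
    "temporal_median_subset",
    "match_coincident",
    "assign_lakes",
]

logger = logging.getLogger(__name__)

BIN_DAYS = 5
N_BINS = 73
_EPS = 1e-9  # guards floor() against float noise at cell boundaries


def doy_bin(dates) -> np.ndarray:
    """5-day seasonal stratum index (1..73) for dates; bin 73 spans 5-6 days."""
    doy = pd.DatetimeIndex(dates).dayofyear.to_numpy()
    return np.minimum((doy - 1) // BIN_DAYS + 1, N_BINS)


def bin_mid_doy(bins) -> np.ndarray:
    """Representative (midpoint) day of year of each 5-day bin."""
    return np.asarray(bins, dtype=int) * BIN_DAYS - 2


def _cell_center(coord: np.ndarray, cell_size: float) -> np.ndarray:
    return np.round(np.floor(coord / cell_size + _EPS) * cell_size + cell_size / 2.0, 6)


def spatial_median_subset(
    native_grid: pd.DataFrame,
    value_col: str,
    cell_size: float = 0.1,
    extra_keys: tuple[str, ...] = ("lake_id",),
) -> pd.DataFrame:
    """Reduce a native-resolution grid to per-cell medians.

    One output row per (timestamp, 0.1-degree cell): the median of all
    non-missing native pixels whose centers fall in the half-open cell.
    Cells without any non-missing pixel are absent from the output.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if native_grid.empty:
        return native_grid.copy()
    df = native_grid.dropna(subset=[value_col]).copy()
    df["lat"] = _cell_center(df["lat"].to_numpy(float), cell_size)
    df["lon"] = _cell_center(df["lon"].to_numpy(float), cell_size)
    keys = [k for k in extra_keys if k in df.columns] + ["date", "lat", "lon"]
    out = df.groupby(keys, as_index=False, sort=True)[value_col].median()
    return out


def temporal_median_subset(
    series: pd.DataFrame,
    value_col: str,
    extra_keys: tuple[str, ...] = ("lake_id",),
) -> pd.DataFrame:
    """Reduce per-pixel daily values to one median per 5-day bin.

    The output row carries the bin's representative (midpoint) date plus
    explicit ``year`` and ``doy_bin`` columns used by all later joins.
    """
    if series.empty:
        out = series.copy()
        for c in ("year", "doy_bin"):
            out[c] = pd.Series(dtype=int)
        return out
    df = series.dropna(subset=[value_col]).copy()
    dates = pd.DatetimeIndex(df["date"])
    df["year"] = dates.year
    df["doy_bin"] = doy_bin(dates)
    keys = [k for k in extra_keys if k in df.columns] + ["lat", "lon", "year", "doy_bin"]
    out = df.groupby(keys, as_index=False, sort=True)[value_col].median()
    out["date"] = pd.to_datetime(out["year"] * 1000 + bin_mid_doy(out["doy_bin"]), format="%Y%j")
    return out


def _check_anchor(df: pd.DataFrame, cell_size: float, name: str) -> None:
    for c in ("lat", "lon"):
        frac = (df[c].to_numpy(float) - cell_size / 2.0) / cell_size
        if np.max(np.abs(frac - np.round(frac))) > 1e-4:
            raise ConfigurationError(
                f"{name} grid {c} coordinates are not centers of {cell_size}-degree cells"
            )


def match_coincident(
    lst_grid: pd.DataFrame,
    chla_grid: pd.DataFrame,
    cell_size: float = 0.1,
) -> pd.DataFrame:
    """Inner-join reduced LST and chl-a grids into coincident pairs.

    Only cells where BOTH variables are present survive.  Both inputs must
    share the cell anchoring convention; mismatched anchors raise a
    configuration error rather than silently producing an empty join.
    """
    if lst_grid.empty or chla_grid.empty:
        cols = ["lake_id", "lat", "lon", "date", "year", "doy_bin", "lst", "chla"]
        return pd.DataFrame(columns=cols)
    _check_anchor(lst_grid, cell_size, "lst")
    _check_anchor(chla_grid, cell_size, "chla")
    keys = [k for k in ("lake_id", "lat", "lon", "year", "doy_bin") if k in lst_grid.columns and k in chla_grid.columns]
    left = lst_grid.rename(columns={}).copy()
    out = left.merge(chla_grid.drop(columns=["date"], errors="ignore"), on=keys, how="inner")
    ordered = [c for c in ("lake_id", "lat", "lon", "date", "year", "doy_bin", "lst", "chla") if c in out.columns]
    return out[ordered]


def assign_lakes(points: pd.DataFrame, lake_masks: pd.DataFrame) -> pd.DataFrame:
    """Label points by the lake mask containing their cell.

    ``lake_masks`` holds (lake_id, lat, lon) cell rows; masks must be
    disjoint.  Points outside every mask are dropped with a logged count.
    """
    dup = lake_masks.duplicated(subset=["lat", "lon"], keep=False)
    if dup.any():
        bad = lake_masks.loc[dup]
        lakes = sorted(bad["lake_id"].unique())
        raise ConfigurationError(f"lake masks overlap (lakes: {', '.join(map(str, lakes))})")
    out = points.drop(columns=["lake_id"], errors="ignore").merge(
        lake_masks[["lake_id", "lat", "lon"]], on=["lat", "lon"], how="left"
    )
    dropped = int(out["lake_id"].isna().sum())
    if dropped:
        logger.info("assign_lakes: dropped %d points outside all lake masks", dropped)
    out = out.dropna(subset=["lake_id"]).reset_index(drop=True)
    cols = ["lake_id"] + [c for c in out.columns if c != "lake_id"]
    return out[cols]
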