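"""Readers, writers and configuration.

CSV is the canonical interchange format (headered, UTF-8, '.' decimal) so
every intermediate is diffable at desk scale; gridded tables can optionally
be exported as NetCDF through xarray.  The observation schema on disk is

    lake_id, lat, lon, date (ISO-8601), year, doy_bin, lst_c, chla_mg_m3

mapped to the internal column names ``lst`` / ``chla`` on read.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, FormatError
from .preprocess import doy_bin

__all__ = [
    "SyntheticBlock",
    "PipelineConfig",
    "read_observations",
    "write_observations",
    "write_netcdf",
    "config_hash",
]

logger = logging.getLogger(__name__)

OBS_COLUMNS = ["lake_id", "lat", "lon", "date", "year", "doy_bin", "lst_c", "chla_mg_m3"]
_RENAME_IN = {"lst_c": "lst", "chla_mg_m3": "chla"}
_RENAME_OUT = {v: k for k, v in _RENAME_IN.items()}


@dataclass
class SyntheticBlock:
    """Stated world of the default synthetic archive."""

    n_lakes: int = 30
    n_pixels_lat: int = 3
    n_pixels_lon: int = 3
    years: int = 15
    amplification: bool = True
    attr_missing_frac: float = 0.1
    summer_prob: float = 0.9
    winter_prob: float = 0.6
    missingness_shape: str = "cos"
    insitu_lakes: int = 5
    insitu_samples: int = 40
    insitu_error_sd_lst: float = 0.4
    insitu_error_bias_chla: float = 1.1
    insitu_error_sd_log_chla: float = 0.2


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips through YAML unchanged."""

    out_dir: str = "results/run"
    observations_path: str | None = None
    catalog_path: str | None = None
    insitu_path: str | None = None
    lake_masks_path: str | None = None
    cell_size: float = 0.1
    bin_days: int = 5
    min_obs: int = 8
    subsample_cap: int = 10_000
    min_trees: int = 1000
    max_trees: int = 10_000
    learning_rate_floor: float = 0.0001
    alpha: float = 0.05
    cv_folds: int = 3
    bag_fraction: float = 0.5
    patience: int = 30
    seeds: dict = field(default_factory=lambda: {"synth": 1, "insitu": 2, "debias": 3, "crosslake": 4})
    synthetic: SyntheticBlock | None = field(default_factory=SyntheticBlock)

    def validate(self) -> None:
        for name in ("cell_size", "min_obs", "subsample_cap", "min_trees", "max_trees", "learning_rate_floor", "alpha"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"config threshold {name} must be positive")
        if self.min_trees >= self.max_trees:
            raise ConfigurationError("min_trees must be < max_trees")
        needed = {"debias", "crosslake"} | ({"synth", "insitu"} if self.synthetic else set())
        missing = sorted(k for k in needed if k not in self.seeds or self.seeds[k] is None)
        if missing:
            raise ConfigurationError(f"missing seeds for stochastic stages: {', '.join(missing)}")
        if self.synthetic is None and self.observations_path is None:
            raise ConfigurationError("either a synthetic block or observations_path is required")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        synth = d.get("synthetic")
        if isinstance(synth, dict):
            d["synthetic"] = SyntheticBlock(**synth)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def read_observations(path) -> pd.DataFrame:
    """Read and validate a paired-observation CSV.

    Malformed rows — non-positive chl-a, non-finite LST, or a stored
    doy_bin inconsistent with the date — are rejected with logged line
    numbers; a missing column is a format error.
    """
    df = pd.read_csv(path)
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    df = df[OBS_COLUMNS].rename(columns=_RENAME_IN)
    df["date"] = pd.to_datetime(df["date"], errors="coerce")
    lineno = df.index.to_numpy() + 2  # header is line 1
    bad_date = df["date"].isna()
    chla = pd.to_numeric(df["chla"], errors="coerce")
    lst = pd.to_numeric(df["lst"], errors="coerce")
    bad_chla = ~(chla > 0)
    bad_lst = ~np.isfinite(lst.to_numpy(dtype=float, na_value=np.nan))
    stored_bin = pd.to_numeric(df["doy_bin"], errors="coerce")
    recomputed = pd.Series(np.nan, index=df.index)
    recomputed.loc[~bad_date] = doy_bin(df.loc[~bad_date, "date"])
    bad_bin = ~bad_date & (stored_bin != recomputed)
    bad = bad_date | bad_chla | bad_lst | bad_bin
    if bad.any():
        for reason, mask in (
            ("unparseable date", bad_date),
            ("non-positive chl-a", bad_chla & ~bad_date),
            ("non-finite LST", bad_lst & ~bad_date & ~bad_chla),
            ("doy_bin inconsistent with date", bad_bin & ~bad_chla & ~bad_lst),
        ):
            if mask.any():
                logger.warning(
                    "%s: rejected %d row(s) (%s) at line(s) %s",
                    path, int(mask.sum()), reason, ", ".join(map(str, lineno[mask][:20])),
                )
        df = df[~bad]
    df = df.copy()
    df["chla"] = chla[~bad] if bad.any() else chla
    df["lst"] = lst[~bad] if bad.any() else lst
    df["year"] = df["year"].astype(int)
    df["doy_bin"] = df["doy_bin"].astype(int)
    return df.reset_index(drop=True)


def write_observations(df: pd.DataFrame, path) -> None:
    out = df.rename(columns=_RENAME_OUT).copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out[OBS_COLUMNS].to_csv(path, index=False)


def write_netcdf(df: pd.DataFrame, path) -> None:
    """Optional NetCDF export of a paired grid with dims (lat, lon, time)."""
    import xarray as xr

    ds = (
        df.set_index(["lat", "lon", "date"])[["lst", "chla"]]
        .to_xarray()
        .rename({"date": "time"})
    )
    ds.attrs["conventions"] = "0.1-degree cell centers; 5-day bin midpoints"
    ds.to_netcdf(path, engine="scipy")
    _ = xr  # keep the import explicit
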