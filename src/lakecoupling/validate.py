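"""Satellite-versus-in-situ validation statistics.

In-situ point samples are matched to their nearest coincident satellite
cell (great-circle distance within a radius, date within a window), and the
paired values are compared with standardized major axis (SMA) regression —
the symmetric line fit appropriate when both variables carry measurement
error — alongside the Pearson correlation and the median absolute error.
The same statistics are applied at the lake level to per-lake summary pairs
(e.g. median chl-a, or the lake-wide correlation coefficients themselves).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .exceptions import DegenerateFitError

__all__ = [
    "MatchedPairs",
    "SMAResult",
    "match_nearest",
    "sma_fit",
    "validation_report",
    "haversine_km",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

#: Default matching bounds: one satellite cell (~4 km at the 0.1-deg scale
#: after subsetting) and one 5-day bin.
DEFAULT_MAX_KM = 4.0
DEFAULT_MAX_DAYS = 5.0


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in kilometres."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(v, dtype=float)) for v in (lat1, lon1, lat2, lon2))
    a = np.sin((lat2 - lat1) / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class SMAResult:
    slope: float
    intercept: float
    slope_ci_low: float
    slope_ci_high: float
    r_squared: float
    n: int

    def covers(self, value: float) -> bool:
        return self.slope_ci_low <= value <= self.slope_ci_high


def match_nearest(
    insitu: pd.DataFrame,
    grid: pd.DataFrame,
    value_col: str,
    insitu_col: str,
    max_km: float = DEFAULT_MAX_KM,
    max_days: float = DEFAULT_MAX_DAYS,
) -> pd.DataFrame:
    """Match each in-situ sample to its nearest coincident satellite cell.

    The candidate minimizing great-circle distance wins, ties broken by the
    smaller temporal offset and then lexicographically by (lat, lon).
    Samples with no candidate within ``max_km`` / ``max_days`` are dropped
    with a logged count.
    """
    if insitu.empty or grid.empty:
        raise ValueError("both the in-situ table and the satellite grid must be non-empty")
    gdates = pd.DatetimeIndex(grid["date"])
    rows = []
    dropped = 0
    for _, s in insitu.iterrows():
        dt_days = np.abs((gdates - pd.Timestamp(s["date"])).total_seconds()) / 86400.0
        cand = grid.loc[dt_days <= max_days].copy()
        if cand.empty:
            dropped += 1
            continue
        cand["temporal_offset"] = dt_days[dt_days <= max_days]
        cand["spatial_offset"] = haversine_km(s["lat"], s["lon"], cand["lat"], cand["lon"])
        cand = cand[cand["spatial_offset"] <= max_km]
        if cand.empty:
            dropped += 1
            continue
        # rank on a millimetre-rounded distance so geometrically equal cells
        # tie exactly and fall through to the temporal then lexical rules
        cand["_dist_key"] = np.round(cand["spatial_offset"], 6)
        best = cand.sort_values(
            ["_dist_key", "temporal_offset", "lat", "lon"], kind="mergesort"
        ).iloc[0]
        rows.append(
            {
                "lake_id": best.get("lake_id", s.get("lake_id")),
                "date": s["date"],
                "insitu_value": s[insitu_col],
                "satellite_value": best[value_col],
                "spatial_offset": float(best["spatial_offset"]),
                "temporal_offset": float(best["temporal_offset"]),
            }
        )
    if dropped:
        logger.info("match_nearest: dropped %d in-situ samples with no coincident cell", dropped)
    out = pd.DataFrame(rows, columns=["lake_id", "date", "insitu_value", "satellite_value", "spatial_offset", "temporal_offset"])
    out.attrs["n_dropped"] = dropped
    return out


def sma_fit(x, y, alpha: float = 0.05) -> SMAResult:
    """Standardized major axis regression of y on x.

    slope = sign(r) * sd(y)/sd(x); the 95% slope interval follows the
    standard F-based construction with n - 2 denominator degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("sma_fit needs at least three points")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        raise DegenerateFitError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    sign = -1.0 if r < 0 else 1.0
    slope = sign * sy / sx
    intercept = float(y.mean() - slope * x.mean())
    r2 = r * r
    # Warton-style CI: B = F * (1 - r^2) / (n - 2)
    f = sstats.f.ppf(1.0 - alpha, 1, n - 2)
    b_term = f * (1.0 - r2) / (n - 2)
    lo = slope * (math.sqrt(b_term + 1.0) - math.sqrt(b_term))
    hi = slope * (math.sqrt(b_term + 1.0) + math.sqrt(b_term))
    if lo > hi:
        lo, hi = hi, lo
    return SMAResult(float(slope), intercept, float(lo), float(hi), float(r2), int(n))


def _variable_stats(matched: pd.DataFrame) -> dict:
    ins = matched["insitu_value"].to_numpy(float)
    sat = matched["satellite_value"].to_numpy(float)
    sma = sma_fit(ins, sat)
    r, p = sstats.pearsonr(ins, sat)
    return {
        "n": len(matched),
        "sma": sma,
        "pearson_r": float(r),
        "pearson_p": float(p),
        "mae": float(np.median(np.abs(ins - sat))),
        "slope_ci_covers_1": sma.covers(1.0),
    }


def validation_report(
    matched: dict[str, pd.DataFrame],
    lake_level: dict[str, pd.DataFrame] | None = None,
) -> dict:
    """Observation-level and lake-level validation statistics.

    ``matched`` maps variable name (e.g. 'lst', 'chla') to a matched-pair
    table; ``lake_level`` maps comparison name to a table with columns
    (lake_id, insitu_value, satellite_value), one row per lake.  Lake-level
    sections with fewer than three lakes are omitted with a notice.
    """
    report: dict = {"observation": {}, "lake_level": {}, "notices": []}
    for var, table in matched.items():
        report["observation"][var] = _variable_stats(table)
    for name, table in (lake_level or {}).items():
        if len(table) < 3:
            report["notices"].append(f"lake-level comparison {name!r} omitted: fewer than 3 lakes")
            continue
        report["lake_level"][name] = _variable_stats(table)
    return report


def report_frame(report: dict) -> pd.DataFrame:
    """Flatten a validation report into a tidy table (one row per section)."""
    rows = []
    for level in ("observation", "lake_level"):
        for name, st in report[level].items():
            sma = st["sma"]
            rows.append(
                {
                    "level": level,
                    "variable": name,
                    "n": st["n"],
                    "slope": sma.slope,
                    "intercept": sma.intercept,
                    "slope_ci_low": sma.slope_ci_low,
                    "slope_ci_high": sma.slope_ci_high,
                    "r_squared": sma.r_squared,
                    "pearson_r": st["pearson_r"],
                    "pearson_p": st["pearson_p"],
                    "mae": st["mae"],
                    "slope_ci_covers_1": st["slope_ci_covers_1"],
                }
            )
    return pd.DataFrame(rows)


def report_text(report: dict) -> str:
    """Human-readable validation summary."""
    lines = ["Satellite vs in-situ validation", "=" * 32]
    df = report_frame(report)
    for _, r in df.iterrows():
        lines.append(
            f"[{r['level']}] {r['variable']}: n={r['n']}, "
            f"SMA slope={r['slope']:.3f} (95% CI {r['slope_ci_low']:.3f}-{r['slope_ci_high']:.3f}, "
            f"covers 1: {bool(r['slope_ci_covers_1'])}), R^2={r['r_squared']:.3f}, "
            f"Pearson r={r['pearson_r']:.3f} (p={r['pearson_p']:.3g}), MAE={r['mae']:.3f}"
        )
    for note in report["notices"]:
        lines.append(f"note: {note}")
    return "\n".join(lines) + "\n"
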