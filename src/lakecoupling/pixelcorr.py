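"""The field of interannual Kendall correlations r_i.

Every (lake, pixel, 5-day seasonal stratum) subdivision holds at most one
coincident (LST, chl-a) pair per year — up to one per simulated year — and
the interannual association within the subdivision is summarized by the
tie-corrected Kendall rank correlation.  Subdivisions with fewer than eight
coincident years, or with degenerate (all-tied) ranks, are counted and
dropped rather than scored.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .stats import kendall_tau

__all__ = ["MIN_OBS", "subdivide", "correlation_field", "kendall_tau"]

logger = logging.getLogger(__name__)

#: Minimum coincident observations for a subdivision to enter the field.
MIN_OBS = 8

_KEYS = ["lake_id", "lat", "lon", "doy_bin"]


def subdivide(pairs: pd.DataFrame) -> pd.DataFrame:
    """Collapse a paired-observation table to one (lst, chla) pair per year
    within each (lake, lat, lon, doy_bin) subdivision.

    Duplicate same-year entries should not occur after 5-day subsetting;
    when they do they collapse to their median with a logged warning.
    """
    if pairs.empty:
        return pd.DataFrame(columns=_KEYS + ["year", "lst", "chla"])
    dup_mask = pairs.duplicated(subset=_KEYS + ["year"], keep=False)
    if dup_mask.any():
        logger.warning(
            "subdivide: %d rows share a (pixel, stratum, year) key; collapsing to medians",
            int(dup_mask.sum()),
        )
        pairs = pairs.groupby(_KEYS + ["year"], as_index=False, sort=True)[["lst", "chla"]].median()
    else:
        pairs = pairs[_KEYS + ["year", "lst", "chla"]].sort_values(_KEYS + ["year"], kind="mergesort")
    return pairs.reset_index(drop=True)


def correlation_field(subdivisions: pd.DataFrame, min_obs: int = MIN_OBS) -> pd.DataFrame:
    """One Kendall correlation record per admissible subdivision.

    Returns columns (lake_id, lat, lon, doy_bin, n_obs, tau, p_value).
    Subdivisions below ``min_obs`` years or with undefined tau (all LST or
    all chl-a values tied) are logged and omitted.
    """
    records = []
    n_small = 0
    n_undefined = 0
    if not subdivisions.empty:
        for key, grp in subdivisions.groupby(_KEYS, sort=True):
            n = len(grp)
            if n < min_obs:
                n_small += 1
                continue
            tau, p = kendall_tau(grp["lst"].to_numpy(), grp["chla"].to_numpy())
            if math.isnan(tau):
                n_undefined += 1
                continue
            records.append(key + (n, tau, p))
    if n_small or n_undefined:
        logger.info(
            "correlation_field: skipped %d subdivisions below %d obs and %d with undefined tau",
            n_small,
            min_obs,
            n_undefined,
        )
    out = pd.DataFrame(records, columns=_KEYS + ["n_obs", "tau", "p_value"])
    out.attrs["n_below_min_obs"] = n_small
    out.attrs["n_undefined_tau"] = n_undefined
    return out


def correlation_field_from_pairs(pairs: pd.DataFrame, min_obs: int = MIN_OBS) -> pd.DataFrame:
    """Convenience: ``subdivide`` followed by ``correlation_field``."""
    return correlation_field(subdivide(pairs), min_obs=min_obs)
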