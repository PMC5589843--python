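"""Spatially and seasonally balanced lake-wide correlations (r_lake).

The stratum correlations r_i are not uniformly distributed over a lake's
pixels and seasons — clouds and ice bias sampling toward particular places
and times of year.  A naive mean of the r_i therefore weights the
best-observed strata most.  The correction fits, per lake, a boosted
regression tree of r_i on (latitude, longitude, day-of-year stratum), then
rebuilds an ensemble of the same size by predicting at pixel/season
combinations resampled *uniformly* from the observed unique lists and
re-attaching the fit's residuals (a permutation of the residual pool, each
used exactly once).  r_lake is the mean of those ensemble members; a
Wilcoxon signed-rank test of the members against zero and a
Benjamini-Hochberg correction across lakes provide the significance flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import brt
from .exceptions import InsufficientDataError
from .stats import wilcoxon_signed_rank

__all__ = [
    "SUBSAMPLE_CAP",
    "LakeSurfaceFit",
    "DebiasEnsemble",
    "LakeSummary",
    "fit_lake_surface",
    "balanced_ensemble",
    "summarize_lake",
    "adjust_multiplicity",
    "debias_lakes",
]

logger = logging.getLogger(__name__)

#: Per-lake training-set cap on the number of stratum correlations.
SUBSAMPLE_CAP = 10_000

_SURFACE_PREDICTORS = ["lat", "lon", "doy_bin"]

#: Minimum ensemble size at which a two-sided signed-rank p < 0.05 is attainable.
MIN_TEST_N = 6


def default_surface_spec(seed: int = 0, **overrides) -> brt.BRTFitSpec:
    """Three predictors (lat, lon, doy) -> interaction depth 3."""
    return brt.BRTFitSpec(interaction_depth=len(_SURFACE_PREDICTORS), seed=seed, **overrides)


@dataclass
class LakeSurfaceFit:
    lake_id: str
    model: brt.BRTModel
    train: pd.DataFrame
    residuals: np.ndarray
    #: True when the tau surface was featureless and the fit fell back to the
    #: floor-rate model (predictions ~ the lake mean; nothing to correct).
    null_surface: bool = False

    @property
    def n(self) -> int:
        return len(self.train)


@dataclass
class DebiasEnsemble:
    lake_id: str
    modeled: np.ndarray
    residuals: np.ndarray
    members: np.ndarray

    @property
    def n(self) -> int:
        return self.members.size


@dataclass
class LakeSummary:
    lake_id: str
    r_lake: float | None = None
    wilcoxon_p: float | None = None
    n: int = 0
    adjusted_p: float | None = None
    adjusted_significant: bool | None = None
    exclusion_reason: str | None = None


def _constant_surface(train: pd.DataFrame, value: float, spec: brt.BRTFitSpec) -> brt.BRTModel:
    """Degenerate zero-tree model for a constant tau field: every prediction
    is the constant and the residual pool is empty-valued (all zeros)."""
    X, categories = brt._encode(train, _SURFACE_PREDICTORS, None)
    return brt.BRTModel(
        trees=[],
        init_value=float(value),
        learning_rate=0.0,
        n_trees_selected=0,
        predictors=list(_SURFACE_PREDICTORS),
        categories=categories,
        relative_influence=pd.Series(
            np.full(len(_SURFACE_PREDICTORS), 100.0 / len(_SURFACE_PREDICTORS)),
            index=_SURFACE_PREDICTORS,
            name="relative_influence",
        ),
        cv_trace=None,
        converged=True,
        spec=spec,
        X_train=X,
    )


def fit_lake_surface(
    records: pd.DataFrame,
    seed: int,
    subsample_cap: int = SUBSAMPLE_CAP,
    spec: brt.BRTFitSpec | None = None,
    lr_grid=brt.LEARNING_RATE_GRID,
) -> LakeSurfaceFit:
    """Fit one lake's tau surface over (lat, lon, doy_bin).

    Lakes with more than ``subsample_cap`` stratum correlations are fit on a
    seeded uniform random subset of exactly that size.  The learning rate is
    tuned on the descending grid unless ``spec.n_trees`` pins the ensemble
    size; an :class:`InsufficientDataError` propagates so the caller can
    eliminate the lake with a reason code.
    """
    lake_ids = records["lake_id"].unique()
    if lake_ids.size != 1:
        raise ValueError(f"fit_lake_surface expects one lake, got {lake_ids.size}")
    lake_id = str(lake_ids[0])
    rng = np.random.default_rng(seed)
    sub = records
    if len(records) > subsample_cap:
        idx = rng.choice(len(records), size=subsample_cap, replace=False)
        sub = records.iloc[np.sort(idx)]
    train = sub[_SURFACE_PREDICTORS + ["tau"]].reset_index(drop=True)

    if spec is None:
        spec = default_surface_spec()
    spec = replace(spec, interaction_depth=len(_SURFACE_PREDICTORS), seed=int(rng.integers(2**31 - 1)))

    tau = train["tau"].to_numpy()
    null_surface = False
    if np.unique(tau).size < 2:
        model = _constant_surface(train[_SURFACE_PREDICTORS], tau[0] if tau.size else 0.0, spec)
    elif spec.n_trees is not None:
        model = brt.fit_brt(train, "tau", spec)
    else:
        try:
            model = brt.tune_learning_rate(train, "tau", spec, grid=lr_grid)
        except InsufficientDataError as exc:
            model = getattr(exc, "model", None)
            if model is None:
                raise
            # Featureless (or too weakly structured) surface: no admissible
            # rate reaches the tree-count window because additional trees do
            # not help.  The tuner's best converged fit — a small ensemble
            # predicting ~ the lake mean — is the correct balancing surface
            # when there is (almost) nothing to correct, so the lake is kept
            # rather than eliminated.
            null_surface = model.n_trees_selected < spec.min_trees
            logger.info(
                "lake %s: tree-count window unreachable; fallback surface with %d trees at lr=%g",
                lake_id, model.n_trees_selected, model.learning_rate,
            )
    residuals = tau - model.predict_encoded(model.X_train)
    return LakeSurfaceFit(
        lake_id=lake_id, model=model, train=train, residuals=residuals, null_surface=null_surface
    )


def balanced_ensemble(fit: LakeSurfaceFit, seed: int, n: int | None = None) -> DebiasEnsemble:
    """Rebuild an ensemble balanced over observed pixels and seasons.

    Each member pairs a prediction at an independently drawn
    (pixel, doy stratum) — uniform with replacement over the unique observed
    lists — with one residual from the pool, consumed without replacement
    (the pool is a permutation; with ``n`` equal to the pool size every
    residual is used exactly once).
    """
    if n is None:
        n = fit.n
    if n > fit.residuals.size:
        raise ValueError("ensemble size cannot exceed the residual pool")
    rng = np.random.default_rng(seed)
    pixels = fit.train[["lat", "lon"]].drop_duplicates().sort_values(["lat", "lon"]).to_numpy()
    strata = np.sort(fit.train["doy_bin"].unique())
    pix = pixels[rng.integers(0, len(pixels), size=n)]
    doy = strata[rng.integers(0, len(strata), size=n)]
    rows = pd.DataFrame({"lat": pix[:, 0], "lon": pix[:, 1], "doy_bin": doy})
    modeled = brt.predict(fit.model, rows)
    residuals = rng.permutation(fit.residuals)[:n]
    return DebiasEnsemble(
        lake_id=fit.lake_id,
        modeled=modeled,
        residuals=residuals,
        members=modeled + residuals,
    )


def summarize_lake(ensemble: DebiasEnsemble) -> LakeSummary:
    """r_lake (mean ensemble member) plus its Wilcoxon signed-rank p-value.

    Ensembles too small for a two-sided p < 0.05 to be attainable are
    summarized without a test (``wilcoxon_p`` is None).
    """
    r_lake = float(ensemble.members.mean())
    if ensemble.n < MIN_TEST_N:
        return LakeSummary(
            lake_id=ensemble.lake_id, r_lake=r_lake, wilcoxon_p=None,
            n=ensemble.n, exclusion_reason="no_test_small_n",
        )
    _, p = wilcoxon_signed_rank(ensemble.members)
    return LakeSummary(lake_id=ensemble.lake_id, r_lake=r_lake, wilcoxon_p=float(p), n=ensemble.n)


def adjust_multiplicity(summaries: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up across all lakes' Wilcoxon p-values."""
    out = summaries.copy()
    out["adjusted_p"] = np.nan
    out["adjusted_significant"] = pd.array([None] * len(out), dtype="boolean")
    mask = out["wilcoxon_p"].notna()
    if mask.any():
        rej, adj, _, _ = multipletests(out.loc[mask, "wilcoxon_p"].to_numpy(), alpha=alpha, method="fdr_bh")
        out.loc[mask, "adjusted_p"] = adj
        out.loc[mask, "adjusted_significant"] = rej
    return out


def debias_lakes(
    field: pd.DataFrame,
    seed: int,
    subsample_cap: int = SUBSAMPLE_CAP,
    spec: brt.BRTFitSpec | None = None,
    alpha: float = 0.05,
    lr_grid=brt.LEARNING_RATE_GRID,
) -> pd.DataFrame:
    """Run the full per-lake debiasing over a correlation-record table.

    Returns one row per lake (columns: lake_id, r_lake, wilcoxon_p, n,
    adjusted_p, adjusted_significant, exclusion_reason); lakes whose surface
    cannot be fit at an admissible learning rate are retained with reason
    ``learning_rate_floor``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for lake_id, records in field.groupby("lake_id", sort=True):
        fit_seed = int(rng.integers(2**31 - 1))
        ens_seed = int(rng.integers(2**31 - 1))
        try:
            fit = fit_lake_surface(records, fit_seed, subsample_cap=subsample_cap, spec=spec, lr_grid=lr_grid)
        except InsufficientDataError as exc:
            logger.info("lake %s eliminated: %s", lake_id, exc)
            rows.append(LakeSummary(lake_id=str(lake_id), n=len(records), exclusion_reason="learning_rate_floor"))
            continue
        ens = balanced_ensemble(fit, ens_seed)
        rows.append(summarize_lake(ens))
    df = pd.DataFrame([vars(s) for s in rows])
    return adjust_multiplicity(df, alpha=alpha)
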