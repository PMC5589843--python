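"""Boosted regression trees: the fitting protocol shared by the per-lake
bias-correction surfaces and the cross-lake attribution model.

The engine is stagewise least-squares gradient boosting over shallow
best-first CART trees (scikit-learn's ``DecisionTreeRegressor`` is the base
inducer).  The protocol layers are what matter here and are implemented
in-repo:

* tree complexity fixed at the number of predictors in the model
  (``interaction_depth`` splits, i.e. ``interaction_depth + 1`` leaves);
* the optimal tree count chosen at the minimum of the cross-validated
  deviance, with an accepted fit required to land in the
  [``min_trees``, ``max_trees``] = [1,000, 10,000] window;
* the learning rate searched on a descending grid down to a floor of
  0.0001, below which the data are declared insufficient;
* non-negative observation weights that scale both the loss and the
  influence accounting;
* missing predictor values routed natively by the base tree's learned
  default split direction (rows are never dropped);
* per-predictor relative influence (weighted squared-error improvement
  summed over all splits, normalized to 100%);
* empirical-marginalization partial dependence.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import sklearn
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

from .exceptions import DegenerateFitError, InsufficientDataError

__all__ = [
    "BRTFitSpec",
    "BRTModel",
    "fit_brt",
    "tune_learning_rate",
    "predict",
    "partial_dependence",
    "save_model",
    "load_model",
    "LEARNING_RATE_GRID",
]

logger = logging.getLogger(__name__)

#: Descending learning-rate search grid; 0.0001 is the admissibility floor.
LEARNING_RATE_GRID = (0.1, 0.05, 0.01, 0.005, 0.001, 0.0005, 0.0001)


@dataclass(frozen=True)
class BRTFitSpec:
    """Fitting protocol parameters.

    ``interaction_depth`` is the number of splits per tree and, per the
    complexity rule, equals the number of predictors in the model.
    ``n_trees`` fixes the ensemble size directly (skipping cross-validated
    selection) — used by diagnostic tests, not by the pipeline.
    ``min_rows`` is a stability guard: tables smaller than this cannot
    support tree-count selection and raise the insufficient-data signal.
    """

    interaction_depth: int
    learning_rate: float = 0.01
    min_trees: int = 1000
    max_trees: int = 10000
    bag_fraction: float = 0.5
    cv_folds: int = 10
    n_trees: int | None = None
    patience: int = 100
    min_rows: int = 30
    weights: np.ndarray | None = field(default=None, repr=False)
    seed: int = 0

    def __post_init__(self):
        if self.interaction_depth < 1:
            raise ValueError("interaction_depth must be >= 1")
        if not (0.0 < self.bag_fraction <= 1.0):
            raise ValueError("bag_fraction must lie in (0, 1]")
        if self.min_trees >= self.max_trees:
            raise ValueError("min_trees must be < max_trees")


@dataclass
class BRTModel:
    """A fitted ensemble plus its training metadata."""

    trees: list
    init_value: float
    learning_rate: float
    n_trees_selected: int
    predictors: list
    categories: dict
    relative_influence: pd.Series
    cv_trace: np.ndarray | None
    converged: bool
    spec: BRTFitSpec
    X_train: np.ndarray = field(repr=False)

    def predict_encoded(self, X: np.ndarray) -> np.ndarray:
        out = np.full(X.shape[0], self.init_value)
        for t in self.trees:
            out += self.learning_rate * t.predict(X)
        return out


# -- encoding ----------------------------------------------------------------


def _is_categorical(s: pd.Series) -> bool:
    return s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool


def _encode(df: pd.DataFrame, predictors: list, categories: dict | None):
    """Predictor matrix as float with NaN for missing; categoricals as codes.

    When ``categories`` is given (predict time), unknown levels are routed
    as missing with a logged count.
    """
    learn = categories is None
    if learn:
        categories = {}
    X = np.empty((len(df), len(predictors)), dtype=float)
    for j, name in enumerate(predictors):
        s = df[name]
        if name in categories or (learn and _is_categorical(s)):
            if learn and name not in categories:
                categories[name] = sorted(s.dropna().astype(str).unique().tolist())
            levels = categories[name]
            codes = s.astype(str).map({lv: i for i, lv in enumerate(levels)})
            unknown = codes.isna() & s.notna()
            if unknown.any() and not learn:
                logger.info("predict: %d unknown %r levels routed as missing", int(unknown.sum()), name)
            X[:, j] = codes.to_numpy(dtype=float, na_value=np.nan)
        else:
            X[:, j] = pd.to_numeric(s).to_numpy(dtype=float, na_value=np.nan)
    return X, categories


# -- boosting core -----------------------------------------------------------


def _boost(X, y, w, lr, max_trees, spec: BRTFitSpec, rng, X_val=None, y_val=None, w_val=None):
    with sklearn.config_context(skip_parameter_validation=True):
        return _boost_inner(X, y, w, lr, max_trees, spec, rng, X_val, y_val, w_val)


def _boost_inner(X, y, w, lr, max_trees, spec: BRTFitSpec, rng, X_val, y_val, w_val):
    """One stagewise boosting run.

    With a validation set, tracks the weighted squared-error deviance after
    every stage and aborts once the running minimum has not improved for
    ``spec.patience`` stages (the trace, not the trees, is the product of a
    validation run).
    """
    n = len(y)
    init = float(np.average(y, weights=w))
    pred = np.full(n, init)
    trees = []
    trace = [] if X_val is not None else None
    if X_val is not None:
        vpred = np.full(len(y_val), init)
        best, best_iter = np.inf, -1
    m_bag = max(2, int(round(spec.bag_fraction * n)))
    uniform_w = bool(np.all(w == w[0]) and w[0] > 0)

    # NaN-free matrices take a fast path that skips sklearn's per-call input
    # validation (float32, check_input=False, raw tree predictions).  Trees
    # with missing values must go through the checked path: the missing-value
    # split support is only engaged during input validation.
    fast = not np.isnan(X).any()
    if fast:
        Xf = np.ascontiguousarray(X, dtype=np.float32)
        Xvf = np.ascontiguousarray(X_val, dtype=np.float32) if X_val is not None else None

    for i in range(max_trees):
        resid = y - pred
        if spec.bag_fraction < 1.0:
            idx = rng.choice(n, size=min(m_bag, n), replace=False)
        else:
            idx = np.arange(n)
        tree = DecisionTreeRegressor(
            max_leaf_nodes=spec.interaction_depth + 1,
            random_state=int(rng.integers(2**31 - 1)),
        )
        if fast:
            tree.fit(Xf[idx], resid[idx], sample_weight=None if uniform_w else w[idx], check_input=False)
            pred += lr * tree.tree_.predict(Xf).ravel()
        else:
            tree.fit(X[idx], resid[idx], sample_weight=w[idx])
            pred += lr * tree.predict(X)
        trees.append(tree)
        if X_val is not None:
            if fast:
                vpred += lr * tree.tree_.predict(Xvf).ravel()
            else:
                vpred += lr * tree.predict(X_val)
            dev = float(np.average((y_val - vpred) ** 2, weights=w_val))
            trace.append(dev)
            if dev < best - 1e-14:
                best, best_iter = dev, i
            elif i - best_iter >= spec.patience:
                break
    return init, trees, (np.asarray(trace) if trace is not None else None)


def _relative_influence(trees, predictors) -> pd.Series:
    raw = np.zeros(len(predictors))
    for t in trees:
        raw += t.tree_.compute_feature_importances(normalize=False)
    total = raw.sum()
    if total <= 0:  # no split ever improved the loss; spread uniformly
        rel = np.full(len(predictors), 100.0 / len(predictors))
    else:
        rel = 100.0 * raw / total
    return pd.Series(rel, index=list(predictors), name="relative_influence")


def fit_brt(table: pd.DataFrame, response: str, spec: BRTFitSpec) -> BRTModel:
    """Fit a weighted boosted regression tree of ``response`` on every other
    column of ``table``.

    Predictor columns are used in sorted-name order so the fit (and hence
    the relative-influence report) does not depend on column order.  The
    tree count is chosen at the minimum of the ``cv_folds``-fold
    cross-validated deviance unless ``spec.n_trees`` fixes it.
    """
    y = pd.to_numeric(table[response]).to_numpy(dtype=float)
    if np.unique(y[~np.isnan(y)]).size < 2:
        raise DegenerateFitError("response is constant; nothing to fit")
    if np.isnan(y).any():
        raise ValueError("response contains missing values")
    if spec.weights is None:
        w = np.ones(len(y))
    else:
        w = np.asarray(spec.weights, dtype=float)
        if w.shape != y.shape:
            raise ValueError("weights length must match the table")
        if (w < 0).any():
            raise ValueError("observation weights must be non-negative")
        if w.sum() <= 0:
            raise ValueError("at least one observation weight must be positive")
    predictors = sorted(c for c in table.columns if c != response)
    if not predictors:
        raise ValueError("table holds no predictor columns")
    X, categories = _encode(table, predictors, None)

    rng = np.random.default_rng(spec.seed)
    cv_seed = int(rng.integers(2**31 - 1))
    fold_seeds = rng.integers(2**31 - 1, size=max(spec.cv_folds, 1))
    final_seed = int(rng.integers(2**31 - 1))

    mean_trace = None
    converged = True
    if spec.n_trees is not None:
        n_sel = int(spec.n_trees)
    else:
        if len(y) < max(spec.min_rows, spec.cv_folds):
            raise InsufficientDataError(
                f"{len(y)} rows cannot support cross-validated tree-count selection"
            )
        folds = KFold(n_splits=spec.cv_folds, shuffle=True, random_state=cv_seed)
        traces = []
        for k, (tr, va) in enumerate(folds.split(X)):
            if np.unique(y[tr]).size < 2 or w[va].sum() <= 0:
                continue
            _, _, trace = _boost(
                X[tr], y[tr], w[tr], spec.learning_rate, spec.max_trees, spec,
                np.random.default_rng(int(fold_seeds[k])),
                X[va], y[va], np.where(w[va].sum() > 0, w[va], 1.0),
            )
            traces.append(trace)
        if not traces:
            raise InsufficientDataError("no usable cross-validation fold")
        L = min(t.size for t in traces)
        mean_trace = np.mean([t[:L] for t in traces], axis=0)
        n_sel = int(np.argmin(mean_trace)) + 1
        # A minimum sitting on the max_trees cap never stabilized.
        converged = not (L >= spec.max_trees and n_sel == L)

    init, trees, _ = _boost(X, y, w, spec.learning_rate, n_sel, spec, np.random.default_rng(final_seed))
    return BRTModel(
        trees=trees,
        init_value=init,
        learning_rate=spec.learning_rate,
        n_trees_selected=n_sel,
        predictors=predictors,
        categories=categories,
        relative_influence=_relative_influence(trees, predictors),
        cv_trace=mean_trace,
        converged=converged,
        spec=spec,
        X_train=X,
    )


def tune_learning_rate(
    table: pd.DataFrame,
    response: str,
    spec_template: BRTFitSpec,
    grid=LEARNING_RATE_GRID,
) -> BRTModel:
    """Descend the learning-rate grid; return the first accepted fit.

    A fit is accepted when its cross-validation-selected tree count lies in
    [``min_trees``, ``max_trees``] and the deviance minimum is interior.
    Exhausting the grid at the 0.0001 floor raises the insufficient-data
    signal so callers can eliminate the lake.

    When structure exists, the selected count grows roughly as 1/learning
    rate, so some admissible rate lands in the window.  When the response
    surface is featureless the selected count stays small at *every* rate;
    that signature (no growth between successive rates once lr <= 0.01) ends
    the search early with the same signal — descending further can never
    reach the window.
    """
    if len(table) < max(spec_template.min_rows, spec_template.cv_folds):
        raise InsufficientDataError(
            f"{len(table)} rows are below the {spec_template.min_rows}-row stability floor"
        )
    prev_selected = None
    last_converged = None
    for lr in grid:
        spec = replace(spec_template, learning_rate=lr, n_trees=None)
        model = fit_brt(table, response, spec)
        if model.converged and spec.min_trees <= model.n_trees_selected <= spec.max_trees:
            return model
        logger.debug(
            "tune_learning_rate: lr=%g rejected (selected %d trees, converged=%s)",
            lr, model.n_trees_selected, model.converged,
        )
        if model.converged:
            last_converged = model
        if (
            lr <= 0.01
            and prev_selected is not None
            and model.n_trees_selected < spec.min_trees
            and model.n_trees_selected <= 1.5 * prev_selected
        ):
            exc = InsufficientDataError(
                f"featureless response surface: selected tree count stalled at "
                f"{model.n_trees_selected} (< {spec.min_trees}) as the learning rate descended"
            )
            exc.model = last_converged  # best available fit, for callers with a fallback policy
            raise exc
        prev_selected = model.n_trees_selected
    exc = InsufficientDataError(
        f"no learning rate >= {grid[-1]} yielded a tree count in "
        f"[{spec_template.min_trees}, {spec_template.max_trees}]"
    )
    exc.model = last_converged
    raise exc


def predict(model: BRTModel, rows: pd.DataFrame) -> np.ndarray:
    """Deterministic ensemble prediction; missing predictors are routed by
    each split's learned default direction, unknown categorical levels are
    treated as missing."""
    missing = [p for p in model.predictors if p not in rows.columns]
    if missing:
        raise ValueError(f"rows lack model predictors: {missing}")
    X, _ = _encode(rows, model.predictors, model.categories)
    return model.predict_encoded(X)


def partial_dependence(model: BRTModel, focal: str, grid) -> pd.DataFrame:
    """Empirical-marginalization partial dependence of ``focal``.

    For each grid value the focal column of the (encoded) training matrix is
    overwritten and predictions are averaged over all training rows.
    """
    if focal not in model.predictors:
        raise ValueError(f"{focal!r} is not a model predictor")
    grid = list(grid)
    if len(grid) == 0:
        raise ValueError("partial-dependence grid is empty")
    j = model.predictors.index(focal)
    if focal in model.categories:
        lookup = {lv: i for i, lv in enumerate(model.categories[focal])}
        enc = [lookup.get(str(g), np.nan) for g in grid]
    else:
        enc = [float(g) for g in grid]
    X = model.X_train.copy()
    effects = []
    for g in enc:
        X[:, j] = g
        effects.append(float(model.predict_encoded(X).mean()))
    return pd.DataFrame({focal: grid, "effect": effects})


# -- serialization -----------------------------------------------------------

_FORMAT = "lakecoupling-brt"
_FORMAT_VERSION = 1


def save_model(model: BRTModel, path) -> None:
    """Versioned on-disk serialization (round-trips predictions exactly)."""
    with open(path, "wb") as fh:
        pickle.dump({"format": _FORMAT, "version": _FORMAT_VERSION, "model": model}, fh)


def load_model(path) -> BRTModel:
    with open(path, "rb") as fh:
        blob = pickle.load(fh)
    if not isinstance(blob, dict) or blob.get("format") != _FORMAT:
        raise ValueError(f"{path} is not a serialized boosted-tree model")
    if blob.get("version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {blob.get('version')}")
    return blob["model"]
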