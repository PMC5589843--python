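"""Boosting-engine tests: influence accounting, weights, missing routing,
tree-count selection, partial dependence, serialization."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from lakecoupling import brt
from lakecoupling.exceptions import DegenerateFitError, InsufficientDataError


class TestFitBasics:
    def test_dominant_predictor_takes_influence(self, small_table, fixed_spec):
        model = brt.fit_brt(small_table, "y", fixed_spec)
        assert model.relative_influence["x1"] > 90.0

    def test_influence_sums_to_100_and_ignores_column_order(self, small_table, fixed_spec):
        a = brt.fit_brt(small_table, "y", fixed_spec)
        permuted = small_table[["x3", "y", "x1", "x2"]]
        b = brt.fit_brt(permuted, "y", fixed_spec)
        assert a.relative_influence.sum() == pytest.approx(100.0, abs=1e-6)
        pd.testing.assert_series_equal(a.relative_influence, b.relative_influence)
        np.testing.assert_array_equal(brt.predict(a, small_table), brt.predict(b, small_table))

    def test_determinism_under_seed(self, small_table):
        spec = brt.BRTFitSpec(interaction_depth=3, learning_rate=0.1, n_trees=100, seed=5)
        a = brt.fit_brt(small_table, "y", spec)
        b = brt.fit_brt(small_table, "y", spec)
        np.testing.assert_array_equal(brt.predict(a, small_table), brt.predict(b, small_table))

    def test_degenerate_and_invalid_inputs(self, small_table):
        const = small_table.assign(y=1.0)
        with pytest.raises(DegenerateFitError):
            brt.fit_brt(const, "y", brt.BRTFitSpec(interaction_depth=3, n_trees=10))
        with pytest.raises(ValueError):
            brt.fit_brt(
                small_table,
                "y",
                brt.BRTFitSpec(interaction_depth=3, n_trees=10, weights=-np.ones(len(small_table))),
            )


class TestWeights:
    def test_single_positive_weight_pins_prediction(self, small_table):
        w = np.zeros(len(small_table))
        w[17] = 1.0
        spec = brt.BRTFitSpec(
            interaction_depth=3, learning_rate=0.3, n_trees=150, bag_fraction=1.0, weights=w, seed=1
        )
        model = brt.fit_brt(small_table, "y", spec)
        pred = brt.predict(model, small_table.iloc[[17]])
        assert pred[0] == pytest.approx(small_table["y"].iloc[17], abs=1e-8)

    def test_duplicating_row_equals_doubling_weight(self, small_table):
        w = np.ones(len(small_table))
        w[0] = 2.0
        spec = brt.BRTFitSpec(
            interaction_depth=3, learning_rate=0.1, n_trees=80, bag_fraction=1.0, seed=3
        )
        weighted = brt.fit_brt(small_table, "y", replace(spec, weights=w))
        duplicated = brt.fit_brt(
            pd.concat([small_table, small_table.iloc[[0]]], ignore_index=True), "y", spec
        )
        np.testing.assert_allclose(
            brt.predict(weighted, small_table), brt.predict(duplicated, small_table), atol=1e-10
        )


class TestMissingAndCategorical:
    def test_missing_predictors_are_routed_not_dropped(self, small_table, fixed_spec):
        holey = small_table.copy()
        holey.loc[::5, "x2"] = np.nan
        model = brt.fit_brt(holey, "y", fixed_spec)
        pred = brt.predict(model, holey)
        assert np.isfinite(pred).all()
        all_missing = pd.DataFrame({"x1": [np.nan], "x2": [np.nan], "x3": [np.nan]})
        assert np.isfinite(brt.predict(model, all_missing)).all()

    def test_unknown_categorical_level_routed_as_missing(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "kind": rng.choice(["fresh", "saline"], 200),
                "x": rng.normal(size=200),
            }
        )
        df["y"] = df["x"] + (df["kind"] == "saline") * 2.0
        spec = brt.BRTFitSpec(interaction_depth=2, learning_rate=0.2, n_trees=100, seed=0)
        model = brt.fit_brt(df, "y", spec)
        novel = pd.DataFrame({"kind": ["brackish"], "x": [0.0]})
        assert np.isfinite(brt.predict(model, novel)).all()


class TestTuneLearningRate:
    def test_structured_lake_fit_lands_in_tree_window(self, seasonal_sign_lake):
        model = seasonal_sign_lake["fit"].model
        assert not seasonal_sign_lake["fit"].null_surface
        assert 1000 <= model.n_trees_selected <= 10000
        assert model.learning_rate >= 0.0001

    def test_ten_row_table_is_insufficient(self):
        rng = np.random.default_rng(1)
        tiny = pd.DataFrame({"x": rng.normal(size=10), "y": rng.normal(size=10)})
        with pytest.raises(InsufficientDataError):
            brt.tune_learning_rate(tiny, "y", brt.BRTFitSpec(interaction_depth=1))


class TestPartialDependence:
    def test_identity_response_gives_identity_curve(self, small_table, fixed_spec):
        model = brt.fit_brt(small_table, "y", fixed_spec)
        x = small_table["x1"]
        grid = np.linspace(x.quantile(0.1), x.quantile(0.9), 15)
        curve = brt.partial_dependence(model, "x1", grid)
        np.testing.assert_allclose(curve["effect"], grid, atol=0.15)
        assert (np.diff(curve["effect"]) >= -1e-9).all()

    def test_never_selected_predictor_is_flat(self, small_table, fixed_spec):
        zero_var = small_table.assign(x3=0.0)  # x3 can never yield a split gain
        model = brt.fit_brt(zero_var, "y", fixed_spec)
        assert model.relative_influence["x3"] == 0.0
        curve = brt.partial_dependence(model, "x3", np.linspace(-2, 2, 9))
        assert np.ptp(curve["effect"]) < 1e-12

    def test_errors(self, small_table, fixed_spec):
        model = brt.fit_brt(small_table, "y", fixed_spec)
        with pytest.raises(ValueError):
            brt.partial_dependence(model, "x1", [])
        with pytest.raises(ValueError):
            brt.partial_dependence(model, "nope", [0.0])


class TestSerialization:
    def test_round_trip_predictions(self, small_table, fixed_spec, tmp_path):
        model = brt.fit_brt(small_table, "y", fixed_spec)
        path = tmp_path / "model.pkl"
        brt.save_model(model, path)
        loaded = brt.load_model(path)
        np.testing.assert_array_equal(brt.predict(model, small_table), brt.predict(loaded, small_table))
        with pytest.raises(ValueError):
            bad = tmp_path / "bad.pkl"
            import pickle

            bad.write_bytes(pickle.dumps({"format": "other"}))
            brt.load_model(bad)
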