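"""Median-filter reduction, coincident matching and lake-assignment tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lakecoupling.exceptions import ConfigurationError
from lakecoupling.preprocess import (
    assign_lakes,
    bin_mid_doy,
    doy_bin,
    match_coincident,
    spatial_median_subset,
    temporal_median_subset,
)


def _grid(lats, lons, values, date="2005-06-01", lake="a"):
    n = len(values)
    return pd.DataFrame(
        {
            "lake_id": [lake] * n,
            "lat": lats,
            "lon": lons,
            "date": pd.to_datetime([date] * n),
            "lst": values,
        }
    )


class TestBins:
    def test_doy_bin_anchoring(self):
        dates = pd.to_datetime(["2005-01-01", "2005-01-05", "2005-01-06", "2005-12-31", "2004-12-31"])
        np.testing.assert_array_equal(doy_bin(dates), [1, 1, 2, 73, 73])  # leap day 366 folds into bin 73

    def test_bin_midpoints(self):
        np.testing.assert_array_equal(bin_mid_doy([1, 2, 73]), [3, 8, 363])


class TestSpatialMedian:
    def test_median_of_three(self):
        g = _grid([0.01, 0.02, 0.03], [0.01, 0.02, 0.03], [1.0, 2.0, 100.0])
        out = spatial_median_subset(g, "lst")
        assert len(out) == 1
        assert out["lst"].iloc[0] == 2.0
        assert out["lat"].iloc[0] == pytest.approx(0.05)  # cell center reported

    def test_even_count_median_matches_sorting_oracle(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        g = _grid([0.01, 0.02, 0.03, 0.04], [0.05] * 4, vals)
        out = spatial_median_subset(g, "lst")
        s = sorted(vals)
        assert out["lst"].iloc[0] == (s[1] + s[2]) / 2 == 2.5

    def test_idempotent_on_matching_resolution(self):
        g = _grid([0.05, 0.15], [0.05, 0.05], [3.0, 4.0])
        once = spatial_median_subset(g, "lst")
        twice = spatial_median_subset(once, "lst")
        pd.testing.assert_frame_equal(once, twice)

    def test_half_open_cell_boundary(self):
        g = _grid([0.0999999, 0.1], [0.05, 0.05], [1.0, 2.0])
        out = spatial_median_subset(g, "lst")
        assert sorted(out["lat"].round(2)) == [0.05, 0.15]  # 0.1 belongs to the upper cell

    def test_empty_and_invalid(self):
        assert spatial_median_subset(_grid([], [], []), "lst").empty
        with pytest.raises(ValueError):
            spatial_median_subset(_grid([0.0], [0.0], [1.0]), "lst", cell_size=0.0)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=12))
    def test_median_containment(self, values):
        g = _grid([0.01] * len(values), [0.01] * len(values), values)
        out = spatial_median_subset(g, "lst")
        assert min(values) <= out["lst"].iloc[0] <= max(values)


class TestTemporalMedian:
    def _series(self, dates, values):
        return pd.DataFrame(
            {"lake_id": "a", "lat": 0.05, "lon": 0.05, "date": pd.to_datetime(dates), "lst": values}
        )

    def test_singleton_and_odd_count(self):
        s = self._series(["2005-01-01"], [7.0])
        assert temporal_median_subset(s, "lst")["lst"].iloc[0] == 7.0
        s = self._series([f"2005-01-0{d}" for d in range(1, 6)], [10.0, 11.0, 12.0, 13.0, 14.0])
        out = temporal_median_subset(s, "lst")
        assert len(out) == 1 and out["lst"].iloc[0] == 12.0
        assert out["doy_bin"].iloc[0] == 1 and out["date"].iloc[0] == pd.Timestamp("2005-01-03")

    def test_constant_series_invariant(self):
        dates = pd.date_range("2005-03-01", periods=30)
        s = self._series(dates, [5.5] * 30)
        out = temporal_median_subset(s, "lst")
        assert (out["lst"] == 5.5).all()
        pd.testing.assert_frame_equal(out, temporal_median_subset(out, "lst")[out.columns])


class TestMatchCoincident:
    def _reduced(self, lats, vals, col):
        df = _grid(lats, [0.05] * len(lats), vals)
        df = df.rename(columns={"lst": col})
        return temporal_median_subset(df, col)

    def test_inner_join_semantics(self):
        lst = self._reduced([0.05, 0.15], [1.0, 2.0], "lst")
        chla = self._reduced([0.05], [3.0], "chla")
        out = match_coincident(lst, chla)
        assert len(out) == 1  # chl-a missing at the second cell
        full = match_coincident(lst, self._reduced([0.05, 0.15], [3.0, 4.0], "chla"))
        assert len(full) == 2
        assert match_coincident(lst, self._reduced([0.95], [3.0], "chla")).empty

    def test_symmetry_in_input_order(self):
        lst = self._reduced([0.05, 0.15], [1.0, 2.0], "lst")
        chla = self._reduced([0.05, 0.15], [3.0, 4.0], "chla")
        a = match_coincident(lst, chla)
        b = match_coincident(chla.rename(columns={"chla": "lst"}), lst.rename(columns={"lst": "chla"}))
        pd.testing.assert_frame_equal(
            a[["lake_id", "lat", "lon", "year", "doy_bin"]],
            b[["lake_id", "lat", "lon", "year", "doy_bin"]],
        )

    def test_mismatched_anchors_raise(self):
        lst = self._reduced([0.05], [1.0], "lst")
        chla = self._reduced([0.05], [3.0], "chla")
        chla["lat"] = 0.07  # not a cell center
        with pytest.raises(ConfigurationError):
            match_coincident(lst, chla)


class TestAssignLakes:
    def test_label_drop_and_overlap(self):
        masks = pd.DataFrame(
            {"lake_id": ["A", "A", "B"], "lat": [0.05, 0.15, 0.25], "lon": [0.05, 0.05, 0.05]}
        )
        pts = pd.DataFrame({"lat": [0.05, 0.25, 0.95], "lon": [0.05, 0.05, 0.05], "v": [1, 2, 3]})
        out = assign_lakes(pts, masks)
        assert out["lake_id"].tolist() == ["A", "B"]  # the off-mask point is dropped
        overlapping = pd.concat(
            [masks, pd.DataFrame({"lake_id": ["B"], "lat": [0.05], "lon": [0.05]})], ignore_index=True
        )
        with pytest.raises(ConfigurationError, match="A.*B|B.*A"):
            assign_lakes(pts, overlapping)
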