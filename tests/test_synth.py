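"""Synthetic-archive generator tests: determinism, positivity, ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from lakecoupling import synth
from lakecoupling.synth import (
    CouplingField,
    LakeScenario,
    MissingnessModel,
    tau_from_rho,
)


class TestCatalog:
    def test_amplification_links_rho_to_trophic_state(self):
        scenarios = synth.generate_lake_catalog(50, seed=7, amplification=True)
        mean_rho = [sc.rho_field().mean() for sc in scenarios]
        log_chla = [np.log10(sc.median_chla_level) for sc in scenarios]
        # the monotone link is imposed by construction: identical rankings
        np.testing.assert_array_equal(sstats.rankdata(mean_rho), sstats.rankdata(log_chla))
        assert sstats.spearmanr(mean_rho, log_chla).statistic == pytest.approx(1.0)
        # zero crossing sits in the interior of the trophic gradient
        assert min(mean_rho) < 0 < max(mean_rho)

    def test_amplification_off_gives_constant_field(self):
        (sc,) = synth.generate_lake_catalog(1, seed=1, amplification=False)
        rho = sc.rho_field()
        assert np.ptp(rho) == 0.0

    def test_catalog_determinism_and_missing_attributes(self):
        a = synth.generate_lake_catalog(10, seed=3, amplification=True)
        b = synth.generate_lake_catalog(10, seed=3, amplification=True)
        pd.testing.assert_frame_equal(synth.catalog_frame(a), synth.catalog_frame(b))
        assert all(np.array_equal(x.rho_field(), y.rho_field()) for x, y in zip(a, b))
        frame = synth.catalog_frame(a)
        missable = frame.drop(columns=["lake_id", "latitude", "median_chla"])
        assert missable.isna().to_numpy().any()  # deliberate attribute gaps
        assert frame["median_chla"].notna().all()

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            synth.generate_lake_catalog(0, seed=1)
        with pytest.raises(ValueError):
            LakeScenario(lake_id="x", years=7)
        with pytest.raises(ValueError):
            LakeScenario(lake_id="x", coupling=CouplingField(base=1.2))


class TestSimulateObservations:
    def test_determinism_positivity_and_truth_consistency(self):
        sc = LakeScenario(lake_id="a", seed=9, n_pixels_lat=4, n_pixels_lon=4)
        obs1, truth1 = synth.simulate_observations(sc)
        obs2, truth2 = synth.simulate_observations(sc)
        pd.testing.assert_frame_equal(obs1, obs2)
        pd.testing.assert_frame_equal(truth1.strata, truth2.strata)
        assert (obs1["chla"] > 0).all()
        assert np.isfinite(obs1["lst"]).all()
        # stored tau must be the closed form of stored rho, exactly
        np.testing.assert_array_equal(
            truth1.strata["true_tau"].to_numpy(), tau_from_rho(truth1.strata["rho"].to_numpy())
        )
        assert truth1.true_r_lake == pytest.approx(truth1.strata["true_tau"].mean())

    def test_zero_retention_gives_empty_observations_with_truth(self):
        sc = LakeScenario(
            lake_id="a", seed=1, n_pixels_lat=2, n_pixels_lon=2,
            missingness=MissingnessModel(summer_prob=0.0, winter_prob=0.0),
        )
        obs, truth = synth.simulate_observations(sc)
        assert obs.empty
        assert len(truth.strata) == 2 * 2 * 73

    def test_independent_anomalies_center_tau_on_zero(self):
        sc = LakeScenario(lake_id="a", seed=21, n_pixels_lat=5, n_pixels_lon=5,
                          coupling=CouplingField(base=0.0))
        obs, _ = synth.simulate_observations(sc)
        from lakecoupling import pixelcorr

        field = pixelcorr.correlation_field_from_pairs(obs)
        assert abs(field["tau"].mean()) < 0.02

    def test_copula_closed_form_constant_rho(self):
        """Grand mean of stratum taus approaches (2/pi) arcsin(rho)."""
        sc = synth.constant_rho_scenario(rho=0.5, seed=2, n_pixels_lat=6, n_pixels_lon=6)
        obs, _ = synth.simulate_observations(sc)
        from lakecoupling import pixelcorr

        field = pixelcorr.correlation_field_from_pairs(obs)
        assert len(field) >= 2000
        assert field["tau"].mean() == pytest.approx(tau_from_rho(0.5), abs=0.02)


class TestInsituSamples:
    def _grid(self, seed=4):
        sc = LakeScenario(lake_id="a", seed=seed, n_pixels_lat=3, n_pixels_lon=3)
        obs, _ = synth.simulate_observations(sc)
        return sc, obs

    def test_zero_error_matches_satellite_exactly(self):
        sc, obs = self._grid()
        ins = synth.simulate_insitu_samples(sc, obs, error_sd_lst=0.0, error_bias_chla=1.0, n_samples=25, seed=8)
        merged = ins.merge(obs, on=["lake_id", "date", "lat", "lon"])
        assert len(merged) == 25
        np.testing.assert_allclose(merged["insitu_lst"], merged["lst"])
        np.testing.assert_allclose(merged["insitu_chla"], merged["chla"])

    def test_boundary_and_invalid_sizes(self):
        sc, obs = self._grid()
        assert len(synth.simulate_insitu_samples(sc, obs, 0.0, 1.0, n_samples=3, seed=1)) == 3
        with pytest.raises(ValueError):
            synth.simulate_insitu_samples(sc, obs, 0.0, 1.0, n_samples=2, seed=1)
        with pytest.raises(ValueError):
            synth.simulate_insitu_samples(sc, obs, 0.0, 1.0, n_samples=len(obs) + 1, seed=1)
        with pytest.raises(ValueError):
            synth.simulate_insitu_samples(sc, obs.iloc[:0], 0.0, 1.0, n_samples=3, seed=1)

    def test_multiplicative_bias_shifts_log_intercept_only(self):
        sc, obs = self._grid()
        ins = synth.simulate_insitu_samples(sc, obs, error_sd_lst=0.0, error_bias_chla=2.0, n_samples=30, seed=8)
        merged = ins.merge(obs, on=["lake_id", "date", "lat", "lon"])
        from lakecoupling.validate import sma_fit

        res = sma_fit(np.log10(merged["insitu_chla"]), np.log10(merged["chla"]))
        assert res.slope == pytest.approx(1.0, abs=1e-9)
        assert res.intercept == pytest.approx(-np.log10(2.0), abs=1e-9)
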