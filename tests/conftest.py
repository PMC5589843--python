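import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from lakecoupling import brt, debias, pixelcorr, synth  # noqa: E402


@pytest.fixture(scope="session")
def fast_spec_kwargs():
    """Reduced protocol settings shared by fit-heavy tests: 3 CV folds and a
    short early-abort patience keep runtimes desk-scale without touching the
    tree-count window or the learning-rate grid."""
    return {"cv_folds": 3, "patience": 30}


@pytest.fixture(scope="session")
def seasonal_sign_lake(fast_spec_kwargs):
    """One seasonal-sign lake with biased sampling plus its fitted surface.

    tau is positive in the summer half of the doy strata and negative in the
    winter half; retention oversamples the positive strata 4:1 (0.8 vs 0.2).
    Shared by the tuning-window and threshold tests.
    """
    sc = synth.LakeScenario(
        lake_id="lake000",
        seed=424,
        n_pixels_lat=3,
        n_pixels_lon=3,
        years=30,
        coupling=synth.CouplingField(base=0.0, seasonal_amp=0.5, shape="step"),
        missingness=synth.MissingnessModel(summer_prob=0.8, winter_prob=0.2, shape="step"),
    )
    obs, truth = synth.simulate_observations(sc)
    field = pixelcorr.correlation_field_from_pairs(obs)
    fit = debias.fit_lake_surface(
        field, seed=425, spec=debias.default_surface_spec(**fast_spec_kwargs)
    )
    return {"scenario": sc, "obs": obs, "truth": truth, "field": field, "fit": fit}


@pytest.fixture()
def small_table():
    """300-row regression table where the response equals one predictor."""
    rng = np.random.default_rng(7)
    df = pd.DataFrame(
        {
            "x1": rng.normal(size=300),
            "x2": rng.normal(size=300),
            "x3": rng.normal(size=300),
        }
    )
    df["y"] = df["x1"].to_numpy().copy()
    return df


@pytest.fixture()
def fixed_spec():
    """Deterministic engine settings for identity-style tests: no CV, no
    bagging, a fixed tree count."""
    return brt.BRTFitSpec(
        interaction_depth=3, learning_rate=0.1, n_trees=200, bag_fraction=1.0, seed=0
    )
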