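import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import runaq as rq
from runaq.pipeline import build_covariate_design

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def desk_study() -> rq.SimulatedStudy:
    """One reduced-scale synthetic cohort (~400 observations) shared across
    tests that only need a realistic fitted pipeline, not fresh randomness."""
    return rq.simulate_study(rq.SimulationConfig.desk_scale(), seed=42)


@pytest.fixture(scope="session")
def desk_model(desk_study):
    """Design pieces for the shared cohort: y, covariates, groups, exposure."""
    races = desk_study.races
    return {
        "y": races["race_time_s"].to_numpy(),
        "X": build_covariate_design(races),
        "race": races["race_id"].to_numpy(),
        "uni": races["university_id"].to_numpy(),
        "exposure": rq.build_exposure_matrix(
            races, desk_study.daily, "pm25", 21
        ),
        "races": races,
        "daily": desk_study.daily,
        "truth": desk_study.truth,
    }


@pytest.fixture(scope="session")
def desk_fit(desk_model):
    """Full-model fit (covariates + df-5/df-5 crossbasis) on the shared cohort."""
    cb = rq.build_crossbasis(
        desk_model["exposure"],
        rq.SplineSpec(df=5),
        rq.SplineSpec(df=5, intercept=True),
    )
    X = pd.concat(
        [
            desk_model["X"],
            pd.DataFrame(
                cb.values, columns=cb.colnames, index=desk_model["X"].index
            ),
        ],
        axis=1,
    )
    fit = rq.fit_lmm(
        desk_model["y"], X, desk_model["race"], desk_model["uni"]
    )
    return fit, cb


def toy_daily(values, location="L0", start="2012-03-01"):
    """A single-location daily table from a plain list of PM2.5 values
    (ozone mirrors PM2.5 scaled into its own range)."""
    dates = pd.date_range(start, periods=len(values), freq="D")
    vals = np.asarray(values, dtype=float)
    return pd.DataFrame(
        {
            "location_id": location,
            "date": dates,
            "pm25": vals,
            "ozone": vals * 3.0,
        }
    )


def toy_races(race_dates, location="L0", university="L0"):
    n = len(race_dates)
    return pd.DataFrame(
        {
            "race_location_id": [location] * n,
            "university_id": [university] * n,
            "race_date": pd.to_datetime(race_dates),
        }
    )
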