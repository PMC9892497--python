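"""Synthetic cohort generator with a known exposure-lag-response surface.

The generator emulates the structure of a collegiate outdoor track season:
universities with rosters of athletes, races hosted at university locations
between March and June, repeated 5-km performances per athlete, daily PM2.5
and ozone series per location, race-day meteorology, and an outcome built
from known fixed effects, a known exposure-lag-response surface, crossed
race/university random intercepts and residual noise.  Because every
component of the truth is retained, each pipeline stage can be tested for
recovery without any external data.

Calibration targets (chosen analytically, once):

* PM2.5 is lognormal when pooled across locations and days.  With pooled
  log-mean 1.9605 and pooled log-sd 0.4415, the 20th/80th percentiles are
  exp(1.9605 ± 0.8416 × 0.4415) = 4.9 / 10.3 μg/m³.  The pooled log-variance
  splits into a between-location part (sd 0.30) and a within-location AR(1)
  part (stationary sd 0.324, lag-1 correlation 0.6).
* Ozone is Gaussian on the raw scale: pooled mean 45.9 and sd 10.695 ppb give
  20th/80th percentiles 36.9 / 54.9; split as between-location sd 6.0 and
  AR(1) stationary sd 8.85, lag-1 correlation 0.6.
* Race times average 857.3 s; covariate moments follow the cohort summary
  table (personal record 844.5 ± 26.3 s, temperature 16.8 ± 7.1 °C, specific
  humidity 8.7 ± 3.8 g/kg, wind 3.7 ± 1.8 m/s, ...).

The default truth surface is linear in concentration with geometrically
decaying lag weights (ratio 0.8, normalized to sum to one), so the cumulative
20th-vs-80th-percentile PM2.5 contrast is slope × Δx ≈ 2.37 × 5.4 ≈ 12.8 s.
A threshold-shaped surface is available for robustness experiments; it lies
outside the crossbasis span and is not used for correctness tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exposure import build_exposure_matrix

__all__ = [
    "SimulatedStudy",
    "SimulationConfig",
    "simulate_cohort",
    "simulate_daily_pollution",
    "simulate_study",
    "true_cumulative_effect",
]

SCHOOL_YEARS = ("freshman", "sophomore", "junior", "senior")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study; defaults match the study scale."""

    # cohort structure
    n_universities: int = 46
    athletes_per_university: int = 7
    n_races: int = 143
    participation_mean: float = 3.4  # mean races per athlete, min 1
    season_start: str = "2012-03-01"
    season_end: str = "2012-06-30"
    buffer_days: int = 28  # daily-series lead-in before the season

    # pollutant model
    pm_log_mean: float = 1.9605
    pm_log_between_sd: float = 0.30
    pm_log_within_sd: float = 0.324
    pm_ar1: float = 0.6
    ozone_mean: float = 45.9
    ozone_between_sd: float = 6.0
    ozone_within_sd: float = 8.85
    ozone_ar1: float = 0.6

    # covariate distributions
    pr_mean: float = 844.5
    pr_sd: float = 26.3
    prev_gap_mean: float = 9.0
    prev_gap_sd: float = 9.0
    days_since_mean: float = 20.4
    days_since_sd: float = 11.0
    temp_mean: float = 16.8
    temp_sd: float = 7.1
    humidity_mean: float = 8.7
    humidity_sd: float = 3.8
    wind_mean: float = 3.7
    wind_sd: float = 1.8
    school_year_probs: tuple[float, ...] = (
        101 / 1104, 257 / 1104, 355 / 1104, 391 / 1104,
    )

    # true outcome model
    mean_time: float = 857.3
    beta_pr: float = 0.75  # s per s of personal record
    beta_prev: float = 0.0  # previous 5-km time carries no signal
    beta_days_since: float = -0.1
    beta_days_into_year: float = -0.05
    beta_temp: float = 0.4
    beta_humidity: float = 0.3
    beta_wind: float = 0.5
    year_offsets: tuple[float, ...] = (0.0, -2.0, -4.0, -6.0)

    # true exposure-lag-response surface
    effect_metric: str = "pm25"
    effect_shape: str = "linear"  # "linear" | "threshold"
    effect_slope: float = 2.37  # s per exposure unit, cumulative over lags
    effect_threshold: float = 0.0
    lag_decay: float = 0.8  # geometric weight ratio across lags
    n_effect_lags: int = 21

    # variance components
    sigma_race: float = 8.0
    sigma_university: float = 5.0
    sigma_resid: float = 12.0

    def __post_init__(self) -> None:
        for name in (
            "pm_log_between_sd", "pm_log_within_sd", "ozone_between_sd",
            "ozone_within_sd", "sigma_race", "sigma_university", "sigma_resid",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.effect_shape not in ("linear", "threshold"):
            raise ValueError("effect_shape must be 'linear' or 'threshold'")
        if not (0 <= self.lag_decay <= 1):
            raise ValueError("lag_decay must be in [0, 1]")
        if abs(sum(self.school_year_probs) - 1.0) > 1e-9:
            raise ValueError("school_year_probs must sum to 1")

    @property
    def lag_weights(self) -> np.ndarray:
        """Per-lag weights w_l, geometrically decaying, summing to one."""
        w = self.lag_decay ** np.arange(self.n_effect_lags, dtype=float)
        return w / w.sum()

    def exposure_response(self, x):
        """The true exposure function g(·), applied elementwise."""
        x = np.asarray(x, dtype=float)
        if self.effect_shape == "linear":
            return self.effect_slope * x
        return self.effect_slope * np.clip(x - self.effect_threshold, 0.0, None)

    @classmethod
    def desk_scale(cls, **overrides) -> "SimulationConfig":
        """A reduced cohort (~400 observations) keeping the study's
        observation:race:university:athlete proportions."""
        base = dict(n_universities=17, athletes_per_university=7, n_races=52)
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class SimulatedStudy:
    races: pd.DataFrame
    daily: pd.DataFrame
    truth: dict


def true_cumulative_effect(
    config: SimulationConfig, x_high: float, x_low: float
) -> float:
    """Closed-form cumulative contrast sum_l w_l (g(x_high) - g(x_low))."""
    g = config.exposure_response
    delta = float(g(x_high)) - float(g(x_low))
    return float(np.sum(config.lag_weights * delta))


def _date_range(config: SimulationConfig) -> pd.DatetimeIndex:
    start = pd.Timestamp(config.season_start) - pd.Timedelta(
        days=config.buffer_days
    )
    return pd.date_range(start, pd.Timestamp(config.season_end), freq="D")


def simulate_daily_pollution(
    config: SimulationConfig, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Seeded per-location daily PM2.5 (μg/m³) and ozone (ppb) series.

    PM2.5 follows a location-specific AR(1) on the log scale (hence strictly
    positive); ozone an AR(1) on the raw scale truncated at zero.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    dates = _date_range(config)
    n_loc, n_day = config.n_universities, dates.size
    locations = [f"U{i:03d}" for i in range(n_loc)]

    pm_levels = config.pm_log_mean + config.pm_log_between_sd * rng.standard_normal(n_loc)
    log_pm = np.empty((n_loc, n_day))
    log_pm[:, 0] = pm_levels + config.pm_log_within_sd * rng.standard_normal(n_loc)
    pm_innov = config.pm_log_within_sd * np.sqrt(max(1.0 - config.pm_ar1**2, 0.0))
    for t in range(1, n_day):
        log_pm[:, t] = (
            pm_levels
            + config.pm_ar1 * (log_pm[:, t - 1] - pm_levels)
            + pm_innov * rng.standard_normal(n_loc)
        )
    pm = np.exp(log_pm)

    o3_levels = config.ozone_mean + config.ozone_between_sd * rng.standard_normal(n_loc)
    o3 = np.empty((n_loc, n_day))
    o3[:, 0] = o3_levels + config.ozone_within_sd * rng.standard_normal(n_loc)
    o3_innov = config.ozone_within_sd * np.sqrt(max(1.0 - config.ozone_ar1**2, 0.0))
    for t in range(1, n_day):
        o3[:, t] = (
            o3_levels
            + config.ozone_ar1 * (o3[:, t - 1] - o3_levels)
            + o3_innov * rng.standard_normal(n_loc)
        )
    o3 = np.clip(o3, 0.0, None)

    return pd.DataFrame(
        {
            "location_id": np.repeat(locations, n_day),
            "date": np.tile(dates, n_loc),
            "pm25": pm.ravel(),
            "ozone": o3.ravel(),
        }
    )


def simulate_cohort(
    config: SimulationConfig,
    daily: pd.DataFrame,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate the race-observation table and return it with ground truth.

    outcome = intercept + lambda' X + sum_l w_l g(x_{i,l})
              + race intercept + university intercept + residual

    where x_{i,l} is the observation's lagged exposure (built with the same
    exposure assembly the analysis pipeline uses).  The intercept is set so
    the cohort mean race time matches ``config.mean_time``.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    universities = [f"U{i:03d}" for i in range(config.n_universities)]
    season = pd.date_range(config.season_start, config.season_end, freq="D")

    race_dates = pd.DatetimeIndex(
        rng.choice(season.to_numpy(), size=config.n_races, replace=True)
    )
    race_hosts = rng.choice(universities, size=config.n_races)
    race_ids = [f"R{i:03d}" for i in range(config.n_races)]
    order = np.argsort(race_dates.to_numpy(), kind="stable")

    # athletes
    n_ath = config.n_universities * config.athletes_per_university
    ath_uni = np.repeat(universities, config.athletes_per_university)
    ath_pr = config.pr_mean + config.pr_sd * rng.standard_normal(n_ath)
    ath_year = rng.choice(SCHOOL_YEARS, size=n_ath, p=config.school_year_probs)

    # race-day meteorology (shared by everyone in a race)
    temp = config.temp_mean + config.temp_sd * rng.standard_normal(config.n_races)
    humid = np.clip(
        config.humidity_mean + config.humidity_sd * rng.standard_normal(config.n_races),
        0.5,
        None,
    )
    speed = np.clip(
        config.wind_mean + config.wind_sd * rng.standard_normal(config.n_races),
        0.1,
        None,
    )
    angle = rng.uniform(0.0, 2.0 * np.pi, size=config.n_races)
    wind_u = speed * np.cos(angle)
    wind_v = speed * np.sin(angle)

    rows = []
    for a in range(n_ath):
        k = 1 + rng.poisson(max(config.participation_mean - 1.0, 0.0))
        k = min(k, config.n_races)
        chosen = rng.choice(config.n_races, size=k, replace=False)
        chosen = chosen[np.argsort(race_dates.to_numpy()[chosen], kind="stable")]
        prev_date = None
        for r in chosen:
            date = race_dates[r]
            if prev_date is not None and date == prev_date:
                continue  # an athlete runs one 5-km per day
            if prev_date is None:
                days_since = max(
                    1.0,
                    rng.normal(config.days_since_mean, config.days_since_sd),
                )
            else:
                days_since = float((date - prev_date).days)
            rows.append(
                {
                    "athlete_id": f"A{a:04d}",
                    "university_id": ath_uni[a],
                    "race_id": race_ids[r],
                    "race_location_id": race_hosts[r],
                    "race_date": date,
                    "school_year": ath_year[a],
                    "personal_record_s": ath_pr[a],
                    "previous_time_s": ath_pr[a]
                    + abs(rng.normal(config.prev_gap_mean, config.prev_gap_sd)),
                    "days_since_previous": round(days_since, 1),
                    "day_of_year": int(date.dayofyear),
                    "temperature_c": temp[r],
                    "specific_humidity_gkg": humid[r],
                    "wind_u_ms": wind_u[r],
                    "wind_v_ms": wind_v[r],
                }
            )
            prev_date = date
    races = pd.DataFrame(rows)
    n = len(races)

    exposure = build_exposure_matrix(
        races, daily, metric=config.effect_metric, n_lags=config.n_effect_lags
    )
    pollution_term = config.exposure_response(exposure.values) @ config.lag_weights

    year_offset = dict(zip(SCHOOL_YEARS, config.year_offsets))
    systematic = (
        config.beta_pr * (races["personal_record_s"] - config.pr_mean)
        + config.beta_prev
        * (races["previous_time_s"] - config.pr_mean - config.prev_gap_mean)
        + config.beta_days_since
        * (races["days_since_previous"] - config.days_since_mean)
        + config.beta_days_into_year
        * (races["day_of_year"] - races["day_of_year"].mean())
        + config.beta_temp * (races["temperature_c"] - config.temp_mean)
        + config.beta_humidity
        * (races["specific_humidity_gkg"] - config.humidity_mean)
        + config.beta_wind
        * (np.hypot(races["wind_u_ms"], races["wind_v_ms"]) - config.wind_mean)
        + races["school_year"].map(year_offset)
    ).to_numpy()

    race_fx = dict(
        zip(race_ids, config.sigma_race * rng.standard_normal(config.n_races))
    )
    uni_fx = dict(
        zip(
            universities,
            config.sigma_university * rng.standard_normal(config.n_universities),
        )
    )
    resid = config.sigma_resid * rng.standard_normal(n)
    intercept = config.mean_time - float(np.mean(systematic + pollution_term))
    races.insert(
        0,
        "race_time_s",
        intercept
        + systematic
        + pollution_term
        + races["race_id"].map(race_fx).to_numpy()
        + races["university_id"].map(uni_fx).to_numpy()
        + resid,
    )

    lo, hi = np.percentile(exposure.values, [20.0, 80.0])
    truth = {
        "intercept": intercept,
        "slopes": {
            "personal_record": config.beta_pr,
            "previous_time": config.beta_prev,
            "days_since_previous": config.beta_days_since,
            "days_into_year": config.beta_days_into_year,
            "temperature": config.beta_temp,
            "specific_humidity": config.beta_humidity,
            "wind_speed": config.beta_wind,
            "year_offsets": dict(zip(SCHOOL_YEARS, config.year_offsets)),
        },
        "effect_metric": config.effect_metric,
        "effect_shape": config.effect_shape,
        "effect_slope": config.effect_slope,
        "lag_weights": config.lag_weights.tolist(),
        "sigma_race": config.sigma_race,
        "sigma_university": config.sigma_university,
        "sigma_resid": config.sigma_resid,
        "race_effects": race_fx,
        "university_effects": uni_fx,
        "exposure_percentiles_20_80": [float(lo), float(hi)],
        "cumulative_contrast_20_80": true_cumulative_effect(config, hi, lo),
    }
    return races, truth


def simulate_study(
    config: SimulationConfig | None = None, seed: int = 0
) -> SimulatedStudy:
    """Simulate the daily pollution table and the cohort in one call."""
    config = config or SimulationConfig()
    ss_daily, ss_cohort = np.random.SeedSequence(seed).spawn(2)
    daily = simulate_daily_pollution(config, np.random.default_rng(ss_daily))
    races, truth = simulate_cohort(config, daily, np.random.default_rng(ss_cohort))
    return SimulatedStudy(races=races, daily=daily, truth=truth)
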