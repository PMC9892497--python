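"""Per-observation lagged exposure histories and race-day covariates.

Each athlete-race observation gets an exposure history over ``L`` days
(default 21: the race day plus the 20 preceding training days).  Lag 0 is the
exposure at the *race* location on the race date; lags 1..L-1 are exposures at
the athlete's *home-university* location on the preceding days, reflecting
where training happened.  Exposure can be measured as raw PM2.5, raw ozone, or
either of the two composite AQI metrics, in which case both pollutants on each
day feed the AQI computation.

Missing (location, date) pairs in the daily table are a hard error listing the
offending keys — no silent imputation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import aqi

__all__ = [
    "ContrastPair",
    "ExposureMatrix",
    "MissingExposureError",
    "METRICS",
    "build_exposure_matrix",
    "percentile_contrast",
    "wind_speed",
]

METRICS = ("pm25", "ozone", "threshold_aqi", "summed_aqi")


class MissingExposureError(ValueError):
    """Daily data absent for one or more required (location, date) keys."""


@dataclass(frozen=True)
class ExposureMatrix:
    """n_observations × L matrix of daily exposure; column l = lag l days."""

    values: np.ndarray
    metric: str
    lags: np.ndarray  # 0 .. L-1

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != self.lags.size:
            raise ValueError("values must be n × L with one column per lag")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("exposure matrix contains non-finite entries")

    @property
    def n_lags(self) -> int:
        return int(self.lags.size)


@dataclass(frozen=True)
class ContrastPair:
    """Exposure values at the low/high percentiles of an exposure pool."""

    x_low: float
    x_high: float

    def __post_init__(self) -> None:
        if self.x_low > self.x_high:
            raise ValueError("x_low must be <= x_high")


def wind_speed(zonal, meridional):
    """Wind speed (m/s) as the hypotenuse of zonal and meridional components."""
    u = np.asarray(zonal, dtype=float)
    v = np.asarray(meridional, dtype=float)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise ValueError("wind components must be finite")
    out = np.hypot(u, v)
    return out if out.ndim else float(out)


def _metric_values(pm: np.ndarray, o3: np.ndarray, metric: str) -> np.ndarray:
    if metric == "pm25":
        return pm
    if metric == "ozone":
        return o3
    pm_idx = aqi.aqi_series(pm, "pm25").astype(float)
    o3_idx = aqi.aqi_series(o3, "ozone").astype(float)
    if metric == "threshold_aqi":
        return np.maximum(pm_idx, o3_idx)
    if metric == "summed_aqi":
        return pm_idx + o3_idx
    raise ValueError(f"unknown exposure metric {metric!r}; choose from {METRICS}")


def build_exposure_matrix(
    races: pd.DataFrame,
    daily: pd.DataFrame,
    metric: str = "pm25",
    n_lags: int = 21,
) -> ExposureMatrix:
    """Assemble the n × L exposure history matrix for every observation.

    Parameters
    ----------
    races
        One row per athlete-race with columns ``race_location_id``,
        ``university_id`` and ``race_date``.
    daily
        Daily pollutant table with columns ``location_id``, ``date``,
        ``pm25`` (μg/m³) and ``ozone`` (ppb); one row per (location, date).
    metric
        One of ``pm25 | ozone | threshold_aqi | summed_aqi``.
    n_lags
        History length L; lag 0 is the race day.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown exposure metric {metric!r}; choose from {METRICS}")
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    n = len(races)
    if n == 0:
        raise ValueError("races table is empty")

    dates = pd.to_datetime(races["race_date"]).dt.normalize().to_numpy()
    locs = np.empty((n, n_lags), dtype=object)
    locs[:, 0] = races["race_location_id"].to_numpy()
    if n_lags > 1:
        locs[:, 1:] = np.repeat(
            races["university_id"].to_numpy()[:, None], n_lags - 1, axis=1
        )
    date_grid = dates[:, None] - np.arange(n_lags) * np.timedelta64(1, "D")

    day = daily.copy()
    day["date"] = pd.to_datetime(day["date"]).dt.normalize()
    indexed = day.set_index(["location_id", "date"])
    if indexed.index.has_duplicates:
        dupes = indexed.index[indexed.index.duplicated()].unique()[:10]
        raise ValueError(f"duplicate (location, date) rows in daily table: {list(dupes)}")

    keys = pd.MultiIndex.from_arrays([locs.ravel(), date_grid.ravel()])
    pulled = indexed[["pm25", "ozone"]].reindex(keys)
    missing = pulled["pm25"].isna().to_numpy() | pulled["ozone"].isna().to_numpy()
    if missing.any():
        bad = keys[missing].unique()
        shown = [(loc, pd.Timestamp(d).date().isoformat()) for loc, d in bad[:10]]
        raise MissingExposureError(
            f"{bad.size} (location, date) keys absent from the daily table; "
            f"first {len(shown)}: {shown}"
        )

    pm = pulled["pm25"].to_numpy().reshape(n, n_lags)
    o3 = pulled["ozone"].to_numpy().reshape(n, n_lags)
    values = _metric_values(pm, o3, metric).astype(float)
    return ExposureMatrix(values=values, metric=metric, lags=np.arange(n_lags))


def percentile_contrast(
    matrix: ExposureMatrix, p_low: float = 20.0, p_high: float = 80.0
) -> ContrastPair:
    """Empirical percentiles pooled over all exposure-matrix entries."""
    if not (0 <= p_low <= p_high <= 100):
        raise ValueError("need 0 <= p_low <= p_high <= 100")
    pool = matrix.values.ravel()
    if pool.size == 0:
        raise ValueError("empty exposure matrix")
    lo, hi = np.percentile(pool, [p_low, p_high])
    return ContrastPair(float(lo), float(hi))
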