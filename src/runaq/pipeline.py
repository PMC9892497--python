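"""End-to-end analysis orchestration: exposure build → covariate selection →
crossbasis selection → mixed-model fit → effect estimation → sensitivity.

The pipeline reads the two CSV schemas below (or in-memory DataFrames with
the same columns), validates them with row-level diagnostics before any
fitting, and writes tidy CSV/JSON outputs plus a run manifest.  Two runs with
identical config and inputs produce byte-identical outputs.

Races table (one row per athlete-race):
    race_time_s, athlete_id, university_id, race_id, race_location_id,
    race_date, school_year, personal_record_s, previous_time_s,
    days_since_previous, day_of_year, temperature_c, specific_humidity_gkg,
    wind_u_ms, wind_v_ms
Daily pollutant table:
    location_id, date (ISO-8601), pm25 (μg/m³), ozone (ppb)
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .crossbasis import CrossBasisMatrix, SplineSpec, build_crossbasis
from .effects import CumulativeEffect, LagResponse, cumulative_effect, lag_response, overall_curve
from .exposure import METRICS, build_exposure_matrix, percentile_contrast, wind_speed
from .mixed import (
    FitResult,
    SelectionResult,
    backward_stepwise_aic,
    default_crossbasis_grid,
    fit_lmm,
    select_crossbasis_form,
)
from .negative_control import NegativeControlReport, run_negative_controls

__all__ = [
    "AnalysisBundle",
    "AnalysisConfig",
    "RACES_COLUMNS",
    "SchemaError",
    "build_covariate_design",
    "load_tables",
    "run_analysis",
]

log = logging.getLogger("runaq")

RACES_COLUMNS = [
    "race_time_s", "athlete_id", "university_id", "race_id",
    "race_location_id", "race_date", "school_year", "personal_record_s",
    "previous_time_s", "days_since_previous", "day_of_year", "temperature_c",
    "specific_humidity_gkg", "wind_u_ms", "wind_v_ms",
]
DAILY_COLUMNS = ["location_id", "date", "pm25", "ozone"]

SCHOOL_YEAR_LEVELS = ("freshman", "sophomore", "junior", "senior")

#: deletable model terms -> design columns (school year is dropped as a block)
COVARIATE_TERMS = {
    "personal_record": ["personal_record_s"],
    "previous_time": ["previous_time_s"],
    "days_since_previous": ["days_since_previous"],
    "school_year": [f"school_year_{l}" for l in SCHOOL_YEAR_LEVELS[1:]],
    "days_into_year": ["day_of_year"],
    "temperature": ["temperature_c"],
    "specific_humidity": ["specific_humidity_gkg"],
    "wind_speed": ["wind_speed"],
}


class SchemaError(ValueError):
    """Input table violates the expected schema."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one pipeline run (one exposure metric)."""

    races_path: str | Path | None = None
    daily_path: str | Path | None = None
    metric: str = "pm25"
    n_lags: int = 21
    percentiles: tuple[float, float] = (20.0, 80.0)
    select_covariates: bool = True
    crossbasis_grid: tuple | None = None  # None -> fixed_spec or default grid
    fixed_spec: tuple[SplineSpec, SplineSpec] | None = (
        SplineSpec(df=5, placement="equal"),
        SplineSpec(df=5, placement="equal", intercept=True),
    )
    n_negative_controls: int = 0
    negative_control_variant: str = "permute"
    seed: int = 0
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        if self.n_lags not in (14, 21, 28):
            raise ValueError("n_lags must be 14, 21 or 28")
        lo, hi = self.percentiles
        if not (0 <= lo <= hi <= 100):
            raise ValueError("percentiles must be ordered within [0, 100]")


@dataclass
class AnalysisBundle:
    """Everything a single run produces."""

    config: AnalysisConfig
    selection: SelectionResult | None
    crossbasis_table: pd.DataFrame | None
    var_spec: SplineSpec
    lag_spec: SplineSpec
    crossbasis: CrossBasisMatrix
    fit: FitResult
    contrast: tuple[float, float]
    cumulative: CumulativeEffect
    lag_curve: LagResponse
    curve: pd.DataFrame
    negative_controls: NegativeControlReport | None
    manifest: dict


def _require_columns(df: pd.DataFrame, cols, name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing columns {missing}")


def validate_tables(races: pd.DataFrame, daily: pd.DataFrame) -> pd.DataFrame:
    """Schema checks with row-level diagnostics; drops incomplete rows.

    Rows with any missing required field are dropped (with a logged count,
    mirroring an explicit exclusion step), not imputed.
    """
    _require_columns(races, RACES_COLUMNS, "races")
    _require_columns(daily, DAILY_COLUMNS, "daily")
    bad_year = ~races["school_year"].isin(SCHOOL_YEAR_LEVELS)
    if bad_year.any():
        raise SchemaError(
            f"unknown school_year values at rows "
            f"{races.index[bad_year][:10].tolist()}"
        )
    complete = races[RACES_COLUMNS].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("dropped %d rows with missing fields", n_dropped)
    return races.loc[complete].reset_index(drop=True)


def load_tables(config: AnalysisConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    if config.races_path is None or config.daily_path is None:
        raise ValueError("config lacks input paths; pass tables directly instead")
    races = pd.read_csv(config.races_path, parse_dates=["race_date"])
    daily = pd.read_csv(config.daily_path, parse_dates=["date"])
    return races, daily


def build_covariate_design(races: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect design: intercept, numeric covariates, school-year
    indicators (freshman reference) and derived wind speed."""
    X = pd.DataFrame(index=races.index)
    X["const"] = 1.0
    for col in (
        "personal_record_s", "previous_time_s", "days_since_previous",
        "day_of_year", "temperature_c", "specific_humidity_gkg",
    ):
        X[col] = races[col].astype(float)
    X["wind_speed"] = wind_speed(
        races["wind_u_ms"].to_numpy(), races["wind_v_ms"].to_numpy()
    )
    for level in SCHOOL_YEAR_LEVELS[1:]:
        X[f"school_year_{level}"] = (races["school_year"] == level).astype(float)
    return X


def run_analysis(
    config: AnalysisConfig,
    races: pd.DataFrame | None = None,
    daily: pd.DataFrame | None = None,
) -> AnalysisBundle:
    """Run the full analysis for one exposure metric.

    Covariate selection (backwards-stepwise AIC on the base model without
    crossbasis terms) runs first; the selected covariate set is then used
    when choosing the crossbasis form and fitting the final model.
    """
    if races is None or daily is None:
        races, daily = load_tables(config)
    races = validate_tables(races, daily)
    log.info("analysis rows: %d", len(races))

    y = races["race_time_s"].to_numpy(dtype=float)
    race_ids = races["race_id"].to_numpy()
    uni_ids = races["university_id"].to_numpy()
    X_full = build_covariate_design(races)

    selection: SelectionResult | None = None
    if config.select_covariates:
        selection = backward_stepwise_aic(
            y, X_full, race_ids, uni_ids, COVARIATE_TERMS
        )
        kept_terms = selection.selected
        log.info("selected covariates: %s (dropped %s)", kept_terms, selection.dropped)
    else:
        kept_terms = sorted(COVARIATE_TERMS)
    kept_cols = ["const"] + [
        c for t in sorted(kept_terms) for c in COVARIATE_TERMS[t]
    ]
    X_cov = X_full[kept_cols]

    exposure = build_exposure_matrix(races, daily, config.metric, config.n_lags)
    contrast = percentile_contrast(exposure, *config.percentiles)

    cb_table = None
    if config.crossbasis_grid is not None or config.fixed_spec is None:
        candidates = (
            list(config.crossbasis_grid)
            if config.crossbasis_grid is not None
            else default_crossbasis_grid()
        )
        (var_spec, lag_spec), cb_table = select_crossbasis_form(
            y, X_cov, exposure, race_ids, uni_ids, candidates
        )
    else:
        var_spec, lag_spec = config.fixed_spec

    cb = build_crossbasis(exposure, var_spec, lag_spec)
    X = pd.concat(
        [X_cov, pd.DataFrame(cb.values, columns=cb.colnames, index=X_cov.index)],
        axis=1,
    )
    fit = fit_lmm(y, X, race_ids, uni_ids)

    cum = cumulative_effect(fit, cb, contrast.x_high, contrast.x_low)
    lag_curve = lag_response(fit, cb, contrast.x_high, contrast.x_low)
    grid = np.linspace(
        np.percentile(exposure.values, 1), np.percentile(exposure.values, 99), 50
    )
    curve = overall_curve(fit, cb, grid, contrast.x_low)

    negative: NegativeControlReport | None = None
    if config.n_negative_controls > 0:
        negative = run_negative_controls(
            y, X_cov, exposure, race_ids, uni_ids,
            cb.var_spec, cb.lag_spec,
            n_iter=config.n_negative_controls,
            seed=config.seed,
            percentiles=config.percentiles,
            variant=config.negative_control_variant,
        )

    manifest = {
        "package": "runaq",
        "version": __version__,
        "metric": config.metric,
        "n_lags": config.n_lags,
        "percentiles": list(config.percentiles),
        "seed": config.seed,
        "n_observations": int(len(races)),
        "n_races": int(pd.unique(race_ids).size),
        "n_universities": int(pd.unique(uni_ids).size),
        "n_athletes": int(races["athlete_id"].nunique()),
        "selected_covariates": sorted(kept_terms),
        "var_spec": var_spec.to_dict() if var_spec.boundary else cb.var_spec.to_dict(),
        "lag_spec": cb.lag_spec.to_dict(),
        "contrast": [contrast.x_low, contrast.x_high],
    }
    bundle = AnalysisBundle(
        config=config,
        selection=selection,
        crossbasis_table=cb_table,
        var_spec=cb.var_spec,
        lag_spec=cb.lag_spec,
        crossbasis=cb,
        fit=fit,
        contrast=(contrast.x_low, contrast.x_high),
        cumulative=cum,
        lag_curve=lag_curve,
        curve=curve,
        negative_controls=negative,
        manifest=manifest,
    )
    if config.out_dir is not None:
        write_bundle(bundle, Path(config.out_dir))
    return bundle


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_bundle(bundle: AnalysisBundle, out_dir: Path) -> None:
    """Write tidy, deterministic CSV/JSON outputs for one run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _dump_json(bundle.manifest, out_dir / "manifest.json")
    _dump_json(bundle.fit.to_dict(), out_dir / "fit.json")
    bundle.fit.coef_table().to_csv(out_dir / "coefficients.csv", index_label="term")
    _dump_json(bundle.cumulative.to_dict(), out_dir / "cumulative_effect.json")
    bundle.lag_curve.table.to_csv(out_dir / "lag_response.csv", index=False)
    bundle.curve.to_csv(out_dir / "overall_curve.csv", index=False)
    if bundle.selection is not None:
        bundle.selection.trace.to_csv(out_dir / "stepwise_trace.csv", index=False)
        _dump_json(
            {
                "selected": sorted(bundle.selection.selected),
                "dropped": bundle.selection.dropped,
            },
            out_dir / "selected_covariates.json",
        )
    if bundle.crossbasis_table is not None:
        bundle.crossbasis_table.to_csv(out_dir / "crossbasis_aic.csv", index=False)
    if bundle.negative_controls is not None:
        _dump_json(
            bundle.negative_controls.to_dict(), out_dir / "negative_controls.json"
        )
        bundle.negative_controls.iterations.to_csv(
            out_dir / "negative_control_iterations.csv", index=False
        )


def plot_bundle(bundle: AnalysisBundle, out_dir: Path) -> None:
    """Optional lag-response / cumulative-curve figures (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    t = bundle.lag_curve.table
    axes[0].fill_between(t["lag"], t["ci_low"], t["ci_high"], color="0.8")
    axes[0].plot(t["lag"], t["estimate"], color="crimson")
    axes[0].axhline(0, color="k", lw=0.5)
    axes[0].set_xlabel("lag (days)")
    axes[0].set_ylabel("race time difference (s)")
    axes[0].set_title(f"lag-response, {bundle.crossbasis.metric}")
    c = bundle.curve
    axes[1].fill_between(c["exposure"], c["ci_low"], c["ci_high"], color="0.8")
    axes[1].plot(c["exposure"], c["estimate"], color="crimson")
    axes[1].axhline(0, color="k", lw=0.5)
    axes[1].set_xlabel(f"{bundle.crossbasis.metric} exposure")
    axes[1].set_ylabel("cumulative difference (s)")
    axes[1].set_title("cumulative association")
    fig.tight_layout()
    fig.savefig(out_dir / f"curves_{bundle.crossbasis.metric}.png", dpi=150)
    plt.close(fig)
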