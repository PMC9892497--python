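"""EPA Air Quality Index (AQI) computation for PM2.5 and 8-hour ozone.

The AQI converts a pollutant concentration into a unitless index by
piecewise-linear interpolation between published concentration breakpoints:

    I = (I_hi - I_lo) / (C_hi - C_lo) * (C - C_lo) + I_lo

where ``[C_lo, C_hi]`` is the breakpoint interval containing the (truncated)
concentration ``C`` and ``[I_lo, I_hi]`` the index range of its category.
Following EPA reporting conventions, PM2.5 (μg/m³) is truncated to one decimal
and ozone (ppb) to an integer before the lookup, and the interpolated index is
rounded half-up to an integer.

Two composite indices over a (PM2.5, ozone) pair are provided:

* :func:`threshold_aqi` — the regulatory index: the maximum of the two
  pollutant-specific indices ("the reported AQI").
* :func:`summed_aqi` — an additive two-pollutant variant: the sum of the
  pollutant-specific indices, treating joint exposure to both pollutants as
  cumulative rather than substitutionary.  It can exceed 500 and carries no
  health-category label.

Breakpoints ship as a CSV resource (``data/aqi_breakpoints.csv``) so they can
be audited or overridden; only the five categories up to "very unhealthy" are
implemented, and concentrations above the last breakpoint raise
:class:`ConcentrationRangeError` rather than being clamped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy import stats

__all__ = [
    "AqiValue",
    "BreakpointRow",
    "BreakpointTable",
    "ConcentrationError",
    "ConcentrationRangeError",
    "aqi_series",
    "kendall_tau",
    "load_breakpoints",
    "pollutant_aqi",
    "summed_aqi",
    "threshold_aqi",
    "truncate_concentration",
]

#: decimal places retained when truncating a concentration before lookup
TRUNCATION_DECIMALS = {"pm25": 1, "ozone": 0}

#: index range required for each implemented category, in order
_CATEGORY_RANGES = {
    "good": (0, 50),
    "moderate": (51, 100),
    "unhealthy-for-sensitive-groups": (101, 150),
    "unhealthy": (151, 200),
    "very-unhealthy": (201, 300),
}


class ConcentrationError(ValueError):
    """Invalid pollutant concentration (negative or non-finite)."""


class ConcentrationRangeError(ConcentrationError):
    """Concentration above the highest implemented breakpoint."""


@dataclass(frozen=True)
class BreakpointRow:
    conc_low: float
    conc_high: float
    index_low: int
    index_high: int
    category: str


@dataclass(frozen=True)
class BreakpointTable:
    """Ordered, contiguous breakpoint rows for one pollutant."""

    pollutant: str
    rows: tuple[BreakpointRow, ...]
    truncation_decimals: int

    def __post_init__(self) -> None:
        step = 10.0 ** (-self.truncation_decimals)
        for i, row in enumerate(self.rows):
            lo, hi = _CATEGORY_RANGES[row.category]
            if (row.index_low, row.index_high) != (lo, hi):
                raise ValueError(
                    f"{self.pollutant} row {i}: index range "
                    f"{row.index_low}-{row.index_high} does not match "
                    f"category {row.category!r}"
                )
            if row.conc_high <= row.conc_low:
                raise ValueError(f"{self.pollutant} row {i}: empty interval")
            if i > 0:
                prev = self.rows[i - 1]
                # contiguity after truncation: successor of conc_high is conc_low
                if abs((prev.conc_high + step) - row.conc_low) > step * 1e-6:
                    raise ValueError(
                        f"{self.pollutant} rows {i - 1}/{i} not contiguous"
                    )

    @property
    def conc_max(self) -> float:
        return self.rows[-1].conc_high

    def row_for(self, truncated_conc: float) -> BreakpointRow:
        for row in self.rows:
            if truncated_conc <= row.conc_high + 1e-9:
                return row
        raise ConcentrationRangeError(
            f"{self.pollutant} concentration {truncated_conc} exceeds the top "
            f"implemented breakpoint {self.conc_max}"
        )


@dataclass(frozen=True)
class AqiValue:
    """An AQI index with its category and per-pollutant components.

    ``category`` is ``None`` for the summed two-pollutant variant, which is
    not an EPA index and has no defined category (it may exceed 500).
    """

    index: int
    category: str | None
    pollutant_indices: dict[str, int]


@lru_cache(maxsize=None)
def load_breakpoints(pollutant: str) -> BreakpointTable:
    """Load the shipped EPA breakpoint table for ``pollutant``."""
    if pollutant not in TRUNCATION_DECIMALS:
        raise KeyError(f"no breakpoint table for pollutant {pollutant!r}")
    rows = []
    path = resources.files("runaq").joinpath("data/aqi_breakpoints.csv")
    with path.open() as handle:
        for rec in csv.DictReader(handle):
            if rec["pollutant"] != pollutant:
                continue
            rows.append(
                BreakpointRow(
                    conc_low=float(rec["conc_low"]),
                    conc_high=float(rec["conc_high"]),
                    index_low=int(rec["index_low"]),
                    index_high=int(rec["index_high"]),
                    category=rec["category"],
                )
            )
    return BreakpointTable(pollutant, tuple(rows), TRUNCATION_DECIMALS[pollutant])


def _round_half_up(x: np.ndarray | float):
    # EPA rounds .5 up; numpy/python round() are banker's rounding.
    # 1e-9 guards against values like 42.99999999 from float division.
    return np.floor(np.asarray(x) + 0.5 + 1e-9).astype(int)


def truncate_concentration(conc, pollutant: str):
    """Truncate (floor) a concentration to the pollutant's lookup precision."""
    table = load_breakpoints(pollutant)
    arr = np.asarray(conc, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ConcentrationError(
            f"{pollutant} concentrations must be finite and >= 0"
        )
    factor = 10.0 ** table.truncation_decimals
    # epsilon compensates for inexact decimals (10.3*10 = 102.999...)
    out = np.floor(arr * factor + 1e-9) / factor
    return out if out.ndim else float(out)


def pollutant_aqi(conc: float, pollutant: str) -> AqiValue:
    """AQI for a single pollutant concentration (PM2.5 μg/m³ or ozone ppb)."""
    table = load_breakpoints(pollutant)
    t = truncate_concentration(conc, pollutant)
    row = table.row_for(t)
    slope = (row.index_high - row.index_low) / (row.conc_high - row.conc_low)
    index = int(_round_half_up(slope * (t - row.conc_low) + row.index_low))
    return AqiValue(index, row.category, {pollutant: index})


def aqi_series(conc, pollutant: str) -> np.ndarray:
    """Vectorized pollutant-specific AQI for an array of concentrations."""
    table = load_breakpoints(pollutant)
    t = np.asarray(truncate_concentration(conc, pollutant), dtype=float)
    too_high = t > table.conc_max + 1e-9
    if np.any(too_high):
        bad = np.asarray(conc, dtype=float)[too_high]
        raise ConcentrationRangeError(
            f"{pollutant} concentrations exceed the top implemented breakpoint "
            f"{table.conc_max}: {np.unique(bad)[:10].tolist()}"
        )
    lows = np.array([r.conc_low for r in table.rows])
    highs = np.array([r.conc_high for r in table.rows])
    ilows = np.array([r.index_low for r in table.rows], dtype=float)
    ihighs = np.array([r.index_high for r in table.rows], dtype=float)
    pos = np.searchsorted(lows, t + 1e-9, side="right") - 1
    slope = (ihighs[pos] - ilows[pos]) / (highs[pos] - lows[pos])
    return _round_half_up(slope * (t - lows[pos]) + ilows[pos])


def _category_for(index: int) -> str:
    for name, (lo, hi) in _CATEGORY_RANGES.items():
        if lo <= index <= hi:
            return name
    raise ValueError(f"index {index} outside implemented category ranges")


def threshold_aqi(pm_conc: float, o3_conc: float) -> AqiValue:
    """Two-pollutant threshold AQI: the max of the per-pollutant indices."""
    pm = pollutant_aqi(pm_conc, "pm25")
    o3 = pollutant_aqi(o3_conc, "ozone")
    index = max(pm.index, o3.index)
    return AqiValue(
        index, _category_for(index), {"pm25": pm.index, "ozone": o3.index}
    )


def summed_aqi(pm_conc: float, o3_conc: float) -> AqiValue:
    """Summed two-pollutant AQI: PM2.5-specific plus ozone-specific index."""
    pm = pollutant_aqi(pm_conc, "pm25")
    o3 = pollutant_aqi(o3_conc, "ozone")
    return AqiValue(
        pm.index + o3.index, None, {"pm25": pm.index, "ozone": o3.index}
    )


def kendall_tau(series_a, series_b) -> tuple[float, float]:
    """Tie-corrected Kendall rank correlation (tau-b) with two-sided p-value.

    Used to compare the agreement between the threshold and summed AQI
    decision indices, whose integerization produces ties.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-d and of equal length")
    if a.size < 2:
        raise ValueError("need at least two observations")
    res = stats.kendalltau(a, b)
    return float(res.statistic), float(res.pvalue)
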