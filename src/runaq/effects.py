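"""Lag-response curves and cumulative effects with delta-method inference.

Every reported effect is a two-point exposure contrast (by default the 80th
vs the 20th percentile of the pooled exposure distribution).  For a contrast
vector v in crossbasis-coefficient space (see
:func:`runaq.crossbasis.contrast_vector`), the point estimate is v'b with
standard error sqrt(v' S v), where b and S are the crossbasis coefficients
and their covariance block from the mixed-model fit.  95% confidence
intervals use the normal multiplier 1.96 (Wald-style, no df correction).

The cumulative effect sums the surface over all lags; the lag-response curve
reports the per-lag contributions, which add up to the cumulative estimate
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crossbasis import CrossBasisMatrix, contrast_vector
from .mixed import FitResult

__all__ = [
    "CumulativeEffect",
    "LagResponse",
    "Z95",
    "cumulative_effect",
    "lag_response",
    "overall_curve",
]

Z95 = 1.96


class MissingCoefficientsError(KeyError):
    """Fit does not contain coefficients for all crossbasis columns."""


@dataclass(frozen=True)
class CumulativeEffect:
    """Cumulative (all-lag) effect of an exposure contrast, in seconds."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    x_low: float
    x_high: float
    metric: str
    n_lags: int

    @property
    def significant(self) -> bool:
        """95% CI excludes zero."""
        return self.ci_low > 0.0 or self.ci_high < 0.0

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "x_low": self.x_low,
            "x_high": self.x_high,
            "metric": self.metric,
            "n_lags": self.n_lags,
            "significant": self.significant,
        }


@dataclass(frozen=True)
class LagResponse:
    """Per-lag effect estimates for a fixed exposure contrast."""

    table: pd.DataFrame  # columns: lag, estimate, se, ci_low, ci_high
    x_low: float
    x_high: float
    metric: str


def _cb_block(fit: FitResult, cb: CrossBasisMatrix):
    names = cb.colnames
    missing = [n for n in names if n not in fit.params.index]
    if missing:
        raise MissingCoefficientsError(
            f"fit lacks coefficients for crossbasis columns {missing}"
        )
    beta = fit.params[names].to_numpy()
    cov = fit.cov.loc[names, names].to_numpy()
    return beta, cov


def cumulative_effect(
    fit: FitResult, cb: CrossBasisMatrix, x_high: float, x_low: float
) -> CumulativeEffect:
    """Cumulative effect of moving exposure from x_low to x_high at all lags."""
    beta, cov = _cb_block(fit, cb)
    v = contrast_vector(cb, x_high, x_low)
    est = float(v @ beta)
    se = float(np.sqrt(max(v @ cov @ v, 0.0)))
    return CumulativeEffect(
        estimate=est,
        se=se,
        ci_low=est - Z95 * se,
        ci_high=est + Z95 * se,
        x_low=float(x_low),
        x_high=float(x_high),
        metric=cb.metric,
        n_lags=int(cb.lags.size),
    )


def lag_response(
    fit: FitResult, cb: CrossBasisMatrix, x_high: float, x_low: float
) -> LagResponse:
    """Per-lag effects of the contrast; rows sum to the cumulative estimate."""
    beta, cov = _cb_block(fit, cb)
    V = np.stack(
        [contrast_vector(cb, x_high, x_low, lag_subset=[l]) for l in cb.lags]
    )
    est = V @ beta
    se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", V, cov, V), 0.0, None))
    table = pd.DataFrame(
        {
            "lag": cb.lags,
            "estimate": est,
            "se": se,
            "ci_low": est - Z95 * se,
            "ci_high": est + Z95 * se,
        }
    )
    return LagResponse(
        table=table, x_low=float(x_low), x_high=float(x_high), metric=cb.metric
    )


def overall_curve(
    fit: FitResult, cb: CrossBasisMatrix, grid, x_reference: float
) -> pd.DataFrame:
    """Cumulative effect at each grid exposure value against a reference.

    The curve is exactly zero at ``x_reference``.  Returns a tidy table with
    columns ``exposure, estimate, se, ci_low, ci_high``.
    """
    beta, cov = _cb_block(fit, cb)
    grid = np.asarray(grid, dtype=float)
    rows = []
    for x in grid:
        v = contrast_vector(cb, x, x_reference)
        est = float(v @ beta)
        se = float(np.sqrt(max(v @ cov @ v, 0.0)))
        rows.append((x, est, se, est - Z95 * se, est + Z95 * se))
    return pd.DataFrame(
        rows, columns=["exposure", "estimate", "se", "ci_low", "ci_high"]
    )
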