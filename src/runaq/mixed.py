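"""Linear mixed models with two crossed random intercepts, fit by ML.

The outcome model is

    y = X b + Z_r d + Z_u g + e,
    d ~ N(0, s2_race I),  g ~ N(0, s2_uni I),  e ~ N(0, s2_resid I),

with Z_r, Z_u indicator matrices for race and home university — *crossed*
(non-nested) grouping factors.  Estimation is full maximum likelihood (not
REML) so that AIC comparisons across different fixed-effect sets are valid.

The likelihood is profiled over the fixed effects and the residual variance:
writing the marginal covariance as s2 * W with
W = I + gamma_r Z_r Z_r' + gamma_u Z_u Z_u' (gamma = variance ratios), the
Woodbury identity reduces every evaluation to operations on the q × q matrix
A = Z'Z + D^{-1} (q = number of groups), so repeated refits — stepwise
selection, crossbasis-form sweeps, negative-control resampling — stay cheap.
Optimization is over the two log variance ratios (L-BFGS-B, multi-start).

Fixed-coefficient covariance is the profiled-ML expression
s2_hat * (X' W^{-1} X)^{-1}, conditional on the estimated variance ratios.
The AIC parameter count is p fixed coefficients + 2 variance components + the
residual variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .crossbasis import SplineSpec, build_crossbasis
from .exposure import ExposureMatrix

__all__ = [
    "ConvergenceError",
    "FitResult",
    "RankDeficiencyError",
    "SelectionResult",
    "backward_stepwise_aic",
    "default_crossbasis_grid",
    "fit_lmm",
    "select_crossbasis_form",
]

_DEFAULT_STARTS = ((-1.0, -1.0), (-5.0, -5.0), (2.0, 2.0))
_ETA_BOUNDS = (-20.0, 12.0)


class RankDeficiencyError(ValueError):
    """Fixed-effect design matrix is not full column rank."""


class ConvergenceError(RuntimeError):
    """Variance-ratio optimization failed from every start."""


@dataclass
class FitResult:
    """Maximum-likelihood fit of the crossed random-intercepts model."""

    params: pd.Series
    cov: pd.DataFrame
    sigma2_race: float
    sigma2_university: float
    sigma2_resid: float
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    eta: tuple[float, float] = (0.0, 0.0)
    optimizer: dict = field(default_factory=dict, repr=False)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def coef_table(self) -> pd.DataFrame:
        se = self.se()
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": se,
                "ci_low": self.params - 1.96 * se,
                "ci_high": self.params + 1.96 * se,
            }
        )

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "cov": self.cov.to_numpy().tolist(),
            "param_names": list(self.params.index),
            "sigma2_race": self.sigma2_race,
            "sigma2_university": self.sigma2_university,
            "sigma2_resid": self.sigma2_resid,
            "loglik": self.loglik,
            "aic": self.aic,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "converged": self.converged,
        }


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    norms = np.linalg.norm(A, axis=0)
    zero = norms == 0.0
    if zero.any():
        raise RankDeficiencyError(
            f"design matrix has all-zero columns: {list(X.columns[zero])}"
        )
    # scale-invariant check: normalize columns, then compare QR pivots
    R = np.linalg.qr(A / norms, mode="r")
    diag = np.abs(np.diag(R))
    bad = [X.columns[i] for i in np.where(diag <= 1e-10 * diag.max())[0]]
    if bad:
        raise RankDeficiencyError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )


def _indicators(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((codes.size, n_levels))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


class _ProfiledLikelihood:
    """Profiled ML deviance as a function of the two log variance ratios."""

    def __init__(self, y, X, race_codes, n_race, uni_codes, n_uni):
        self.n, self.p = X.shape
        Z = np.hstack(
            [_indicators(race_codes, n_race), _indicators(uni_codes, n_uni)]
        )
        self.n_race, self.n_uni = n_race, n_uni
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _solve(self, eta):
        g_r, g_u = np.exp(eta)
        d = np.concatenate(
            [np.full(self.n_race, g_r), np.full(self.n_uni, g_u)]
        )
        A = self.ZtZ + np.diag(1.0 / d)
        cA = cho_factor(A, lower=True)
        logdet_w = 2.0 * np.sum(np.log(np.diag(cA[0]))) + np.sum(np.log(d))
        AiZtX = cho_solve(cA, self.ZtX)
        AiZty = cho_solve(cA, self.Zty)
        S_xx = self.XtX - self.ZtX.T @ AiZtX
        S_xy = self.Xty - self.ZtX.T @ AiZty
        S_yy = self.yty - self.Zty @ AiZty
        beta = np.linalg.solve(S_xx, S_xy)
        rss = max(float(S_yy - beta @ S_xy), 1e-300)
        sigma2 = rss / self.n
        return beta, sigma2, logdet_w, S_xx

    def nll(self, eta) -> float:
        _, sigma2, logdet_w, _ = self._solve(eta)
        return 0.5 * (
            self.n * np.log(2.0 * np.pi * sigma2) + logdet_w + self.n
        )


def fit_lmm(
    y,
    X: pd.DataFrame,
    race_ids,
    university_ids,
    starts: Sequence[tuple[float, float]] | None = None,
) -> FitResult:
    """Fit the crossed random-intercepts model by maximum likelihood.

    Parameters
    ----------
    y
        Outcome vector (altitude-adjusted race time, seconds).
    X
        Fixed-effect design matrix as a labelled DataFrame (include an
        intercept column explicitly).
    race_ids, university_ids
        Grouping labels for the two crossed random intercepts.
    starts
        Optional optimizer starts in (log gamma_race, log gamma_uni) space;
        a single warm start makes repeated refits cheap.
    """
    y = np.asarray(y, dtype=float)
    if len(X) != y.size:
        raise ValueError("outcome and design dimensions disagree")
    _check_rank(X)
    race_codes, race_levels = pd.factorize(np.asarray(race_ids))
    uni_codes, uni_levels = pd.factorize(np.asarray(university_ids))
    if race_codes.size != y.size or uni_codes.size != y.size:
        raise ValueError("grouping factor lengths disagree with outcome")

    prof = _ProfiledLikelihood(
        y, X.to_numpy(dtype=float), race_codes, race_levels.size,
        uni_codes, uni_levels.size,
    )
    results = []
    for x0 in starts if starts is not None else _DEFAULT_STARTS:
        res = minimize(
            prof.nll,
            np.asarray(x0, dtype=float),
            method="Nelder-Mead",
            bounds=[_ETA_BOUNDS, _ETA_BOUNDS],
            options={"xatol": 1e-5, "fatol": 1e-9, "maxiter": 500},
        )
        results.append(res)
    # the profiled deviance is flat in a ratio that shrinks to zero, so a
    # maxiter stop on that ridge is still a usable optimum; reject only
    # starts that produced no finite objective at all
    ok = [r for r in results if np.isfinite(r.fun)]
    if not ok:
        raise ConvergenceError(
            "variance-ratio optimization failed; traces: "
            + "; ".join(str(r.message) for r in results)
        )
    best = min(ok, key=lambda r: r.fun)
    eta = best.x
    beta, sigma2, _, S_xx = prof._solve(eta)
    g_r, g_u = np.exp(eta)
    cov = sigma2 * np.linalg.inv(S_xx)
    cov = (cov + cov.T) / 2.0
    p = X.shape[1]
    return FitResult(
        params=pd.Series(beta, index=X.columns),
        cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        sigma2_race=float(g_r * sigma2),
        sigma2_university=float(g_u * sigma2),
        sigma2_resid=float(sigma2),
        loglik=float(-best.fun),
        n_params=p + 3,
        n_obs=int(y.size),
        converged=bool(best.success),
        eta=(float(eta[0]), float(eta[1])),
        optimizer={"n_starts": len(results), "nit": int(best.nit)},
    )


@dataclass
class SelectionResult:
    """Outcome of a backwards-stepwise AIC covariate selection."""

    selected: list[str]
    dropped: list[str]
    trace: pd.DataFrame
    fit: FitResult


def backward_stepwise_aic(
    y,
    X: pd.DataFrame,
    race_ids,
    university_ids,
    terms: Mapping[str, Sequence[str]],
    always: Sequence[str] = ("const",),
) -> SelectionResult:
    """Backwards-stepwise covariate selection by AIC on the base model.

    ``terms`` maps a deletable term name to the design columns it owns (a
    categorical term owns all its indicator columns and is dropped as a
    block).  At each step the single term whose removal most decreases AIC is
    deleted; selection stops when no deletion decreases AIC.  Columns in
    ``always`` (the intercept, and any crossbasis columns if present in X)
    are never deletion candidates.  Deterministic given the data.
    """
    if not terms:
        raise ValueError("need at least one candidate term")
    current = sorted(terms)

    def model_cols(active: Sequence[str]) -> list[str]:
        cols = [c for c in always]
        for t in active:
            cols.extend(terms[t])
        return cols

    fit = fit_lmm(y, X[model_cols(current)], race_ids, university_ids)
    rows = [{"step": 0, "removed": None, "aic": fit.aic}]
    dropped: list[str] = []
    step = 0
    while current:
        candidates = []
        for t in current:
            trial = [u for u in current if u != t]
            trial_fit = fit_lmm(
                y, X[model_cols(trial)], race_ids, university_ids
            )
            candidates.append((trial_fit.aic, t, trial_fit))
        best_aic, best_term, best_fit = min(candidates, key=lambda c: (c[0], c[1]))
        if best_aic >= fit.aic:
            break
        step += 1
        current = [u for u in current if u != best_term]
        dropped.append(best_term)
        fit = best_fit
        rows.append({"step": step, "removed": best_term, "aic": fit.aic})
    return SelectionResult(
        selected=current,
        dropped=dropped,
        trace=pd.DataFrame(rows),
        fit=fit,
    )


def default_crossbasis_grid(
    dfs: Sequence[int] = (3, 4, 5),
    placements: Sequence[str] = ("equal", "log"),
) -> list[tuple[SplineSpec, SplineSpec]]:
    """All (var_spec, lag_spec) candidates over a df × placement grid.

    Exposure-dimension bases carry no intercept (absorbed by the model
    intercept); lag-dimension bases include one so lag-0 effects are free.
    """
    var_specs = [
        SplineSpec(df=df, placement=pl) for df in dfs for pl in placements
    ]
    lag_specs = [
        SplineSpec(df=df, placement=pl, intercept=True)
        for df in dfs
        for pl in placements
    ]
    return [(v, l) for v in var_specs for l in lag_specs]


def select_crossbasis_form(
    y,
    X_cov: pd.DataFrame,
    exposure: ExposureMatrix,
    race_ids,
    university_ids,
    candidates: Sequence[tuple[SplineSpec, SplineSpec]] | None = None,
) -> tuple[tuple[SplineSpec, SplineSpec], pd.DataFrame]:
    """AIC selection of the crossbasis functional form.

    Refits the full model (covariates + crossbasis) for every candidate
    (var_spec, lag_spec) pair and returns the AIC-minimizing pair together
    with the full AIC table.  Ties break toward smaller total df, then toward
    equal knot placement.  Per-candidate fit failures are recorded in the
    table rather than aborting the sweep.
    """
    if candidates is None:
        candidates = default_crossbasis_grid()
    if not candidates:
        raise ValueError("need at least one candidate crossbasis form")
    rows = []
    fits: dict[int, tuple[SplineSpec, SplineSpec]] = {}
    for i, (vspec, lspec) in enumerate(candidates):
        row = {
            "var_df": vspec.df,
            "var_placement": vspec.placement,
            "lag_df": lspec.df,
            "lag_placement": lspec.placement,
            "n_basis_cols": vspec.df * lspec.df,
            "aic": np.nan,
            "error": "",
        }
        try:
            cb = build_crossbasis(exposure, vspec, lspec)
            cb_df = pd.DataFrame(
                cb.values, columns=cb.colnames, index=X_cov.index
            )
            X = pd.concat([X_cov, cb_df], axis=1)
            fit = fit_lmm(y, X, race_ids, university_ids)
            row["aic"] = fit.aic
            fits[i] = (vspec, lspec)
        except (RankDeficiencyError, ConvergenceError, ValueError) as exc:
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    table = pd.DataFrame(rows)
    if not fits:
        raise ConvergenceError("every candidate crossbasis form failed to fit")

    def sort_key(i: int):
        v, l = fits[i]
        n_log = (v.placement == "log") + (l.placement == "log")
        return (table.loc[i, "aic"], v.df + l.df, n_log)

    best_i = min(fits, key=sort_key)
    return fits[best_i], table
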