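"""Natural cubic spline bases and the DLNM tensor-product crossbasis.

A distributed-lag non-linear model represents the exposure-lag-response
surface with a *crossbasis*: the tensor product of a basis over exposure
intensity and a basis over lag.  For observation i with exposure history
x_{i,0..L-1}, the crossbasis column (j, k) is

    T_{i,(j,k)} = sum_l R_j(x_{i,l}) * C_k(l)

where R_j are exposure-dimension basis functions and C_k lag-dimension basis
functions.  Regression coefficients on these columns parameterize the smooth
surface; effect contrasts are linear functionals of the coefficients (see
:func:`contrast_vector`).

The default basis is a natural cubic spline without intercept: piecewise cubic,
C² continuous, constrained to be *linear* beyond its boundary knots, with
``df`` columns and ``df - 1`` internal knots.  It is built from the truncated
power representation

    N_1(x) = x,   N_{m+1}(x) = d_m(x) - d_{K-2}(x),
    d_m(x) = [ (x - ξ_m)_+³ - (x - ξ_{K-1})_+³ ] / (ξ_{K-1} - ξ_m)

over knots ξ_0 < ... < ξ_{K-1} (K = df + 1, boundary knots included), which
spans exactly the natural cubic splines on those knots minus the constant.
Because the basis contains no intercept, only two-point contrasts — which are
free of any centering constant — are reported downstream.

``kind="linear"`` (basis = x) and ``kind="const"`` (basis = 1) are degenerate
single-column bases used for linear-limit reductions: with R = x and C = 1 the
crossbasis collapses to the 21-day moving sum of exposure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .exposure import ExposureMatrix

__all__ = [
    "CrossBasisMatrix",
    "ExtrapolationWarning",
    "SplineSpec",
    "build_crossbasis",
    "contrast_vector",
    "natural_cubic_basis",
]


class ExtrapolationWarning(UserWarning):
    """Contrast requested outside the basis boundary range (natural linear
    extension used)."""


@dataclass(frozen=True)
class SplineSpec:
    """Specification of a one-dimensional basis.

    Parameters
    ----------
    df
        Degrees of freedom = number of basis columns (no intercept).
    placement
        ``"equal"``: internal knots at equally spaced quantile positions when
        the spec is resolved against data (for the uniform lag grid this is
        identical to equal spacing on the value range; for a skewed exposure
        distribution it keeps every knot interval populated), or equally
        spaced over the boundary range when only a boundary is given;
        ``"log"``: equally spaced on log(t + 1) — intended for the lag
        dimension so that knots concentrate at recent lags.
    kind
        ``"ns"`` natural cubic spline (default), ``"linear"`` identity basis,
        ``"const"`` all-ones basis (the latter two require df = 1).
    intercept
        Include a constant column (counted in ``df``).  Standard for the
        *lag* dimension — without it every representable lag curve would be
        pinned to zero at lag 0 — and off for the exposure dimension, whose
        level is absorbed by the model intercept.
    boundary
        (low, high) boundary knots; ``None`` until resolved against data.
    internal_knots
        Explicit internal knot locations; normally filled in by
        :meth:`resolve` and carried in metadata so predictions are
        reproducible.
    """

    df: int
    placement: str = "equal"
    kind: str = "ns"
    intercept: bool = False
    boundary: tuple[float, float] | None = None
    internal_knots: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if self.placement not in ("equal", "log"):
            raise ValueError("placement must be 'equal' or 'log'")
        if self.kind not in ("ns", "linear", "const"):
            raise ValueError("kind must be 'ns', 'linear' or 'const'")
        if self.kind in ("linear", "const") and self.df != 1:
            raise ValueError(f"kind {self.kind!r} requires df = 1")
        if self.intercept and self.kind != "ns":
            raise ValueError("intercept only applies to the ns kind")
        if self.boundary is not None and self.boundary[1] <= self.boundary[0]:
            raise ValueError("degenerate boundary range")
        if self.internal_knots is not None:
            ks = np.asarray(self.internal_knots)
            if ks.size != max(self.spline_df - 1, 0) and self.kind == "ns":
                raise ValueError(f"need {max(self.spline_df - 1, 0)} internal knots")
            if ks.size > 1 and np.any(np.diff(ks) <= 0):
                raise ValueError("internal knots must be strictly increasing")

    @property
    def spline_df(self) -> int:
        """Columns contributed by the spline itself (df minus the intercept)."""
        return self.df - int(self.intercept)

    def resolve(self, data) -> "SplineSpec":
        """Fill in boundary and internal knots from observed values."""
        data = np.asarray(data, dtype=float)
        low, high = float(data.min()), float(data.max())
        if self.boundary is not None:
            low, high = self.boundary
        elif high <= low:
            raise ValueError("degenerate boundary range")
        spec = replace(self, boundary=(low, high))
        if (
            spec.kind != "ns"
            or spec.spline_df <= 1
            or spec.internal_knots is not None
        ):
            return spec
        if spec.placement == "equal":
            probs = np.linspace(0.0, 1.0, spec.spline_df + 1)[1:-1]
            internal = np.quantile(data, probs)
        else:
            internal = _log_knots(low, high, spec.spline_df)
        if np.unique(internal).size < internal.size or (
            internal[0] <= low or internal[-1] >= high
        ):
            raise ValueError(
                "degenerate data: resolved internal knots are not strictly "
                f"inside the boundary and distinct ({internal.tolist()})"
            )
        return replace(spec, internal_knots=tuple(float(k) for k in internal))

    def knots(self) -> np.ndarray:
        """All knots, boundary included (K = df + 1 for the ns kind)."""
        if self.boundary is None:
            raise ValueError("boundary knots not resolved")
        b0, b1 = self.boundary
        if self.kind != "ns" or self.spline_df <= 1:
            return np.array([b0, b1])
        if self.internal_knots is not None:
            return np.concatenate([[b0], self.internal_knots, [b1]])
        if self.placement == "equal":
            return np.linspace(b0, b1, self.spline_df + 1)
        return np.concatenate([[b0], _log_knots(b0, b1, self.spline_df), [b1]])

    def to_dict(self) -> dict:
        return {
            "df": self.df,
            "placement": self.placement,
            "kind": self.kind,
            "intercept": self.intercept,
            "boundary": list(self.boundary) if self.boundary else None,
            "internal_knots": (
                list(self.internal_knots)
                if self.internal_knots is not None
                else None
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        b = d.get("boundary")
        ks = d.get("internal_knots")
        return cls(
            df=d["df"],
            placement=d.get("placement", "equal"),
            kind=d.get("kind", "ns"),
            intercept=d.get("intercept", False),
            boundary=tuple(b) if b else None,
            internal_knots=tuple(ks) if ks else None,
        )


def _log_knots(low: float, high: float, df: int) -> np.ndarray:
    if low < 0:
        raise ValueError("log placement requires a non-negative range")
    return np.expm1(np.linspace(np.log1p(low), np.log1p(high), df + 1))[1:-1]


def natural_cubic_basis(points, spec: SplineSpec) -> np.ndarray:
    """Evaluate the basis at ``points``; returns an n_points × df matrix."""
    x = np.atleast_1d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("basis points must be finite")
    if spec.kind == "const":
        return np.ones((x.size, 1))
    if spec.kind == "linear":
        return x[:, None].copy()
    sdf = spec.spline_df
    if sdf == 0:  # intercept-only
        return np.ones((x.size, 1))
    if sdf == 1:
        core = x[:, None].copy()
    else:
        knots = spec.knots()
        k_last = knots[-1]
        # common rescale keeps cubic columns on the order of the linear one
        scale = (k_last - knots[0]) ** 2

        def d(m: int) -> np.ndarray:
            return (
                np.clip(x - knots[m], 0.0, None) ** 3
                - np.clip(x - k_last, 0.0, None) ** 3
            ) / (k_last - knots[m])

        d_pen = d(len(knots) - 2)
        cols = [x] + [(d(m) - d_pen) / scale for m in range(len(knots) - 2)]
        core = np.column_stack(cols)
    if spec.intercept:
        return np.column_stack([np.ones(x.size), core])
    return core


@dataclass(frozen=True)
class CrossBasisMatrix:
    """n × (df_var · df_lag) crossbasis with the metadata to reproduce it."""

    values: np.ndarray
    var_spec: SplineSpec
    lag_spec: SplineSpec
    lags: np.ndarray
    metric: str = "exposure"

    def __post_init__(self) -> None:
        expected = self.var_spec.df * self.lag_spec.df
        if self.values.shape[1] != expected:
            raise ValueError("column count must equal df_var × df_lag")

    @property
    def colnames(self) -> list[str]:
        return [
            f"cb{j}_{k}"
            for j in range(self.var_spec.df)
            for k in range(self.lag_spec.df)
        ]

    def lag_basis(self) -> np.ndarray:
        """L × df_lag basis evaluated at the integer lags."""
        return natural_cubic_basis(self.lags.astype(float), self.lag_spec)

    def var_basis(self, x) -> np.ndarray:
        """Exposure-dimension basis evaluated at arbitrary exposure values."""
        return natural_cubic_basis(x, self.var_spec)

    def metadata(self) -> dict:
        """JSON-serializable description sufficient for exact refitting."""
        return {
            "metric": self.metric,
            "var_spec": self.var_spec.to_dict(),
            "lag_spec": self.lag_spec.to_dict(),
            "lags": self.lags.tolist(),
        }


def build_crossbasis(
    exposure: ExposureMatrix | np.ndarray,
    var_spec: SplineSpec,
    lag_spec: SplineSpec,
    metric: str | None = None,
) -> CrossBasisMatrix:
    """Build the tensor-product crossbasis of an exposure-history matrix.

    Exposure-dimension boundary knots default to the observed exposure range;
    the lag dimension spans [0, L-1].  Both resolved specs are stored so the
    matrix is reproducible from metadata alone.
    """
    if isinstance(exposure, ExposureMatrix):
        X = exposure.values
        lags = exposure.lags
        metric = metric or exposure.metric
    else:
        X = np.asarray(exposure, dtype=float)
        if X.ndim != 2:
            raise ValueError("exposure must be a 2-d (n × L) array")
        lags = np.arange(X.shape[1])
        metric = metric or "exposure"
    n, L = X.shape
    vspec = var_spec.resolve(X.ravel())
    lspec = lag_spec.resolve(lags.astype(float))
    R = natural_cubic_basis(X.ravel(), vspec).reshape(n, L, vspec.df)
    C = natural_cubic_basis(lags.astype(float), lspec)
    values = np.einsum("nlj,lk->njk", R, C).reshape(n, vspec.df * lspec.df)
    return CrossBasisMatrix(
        values=values, var_spec=vspec, lag_spec=lspec, lags=lags, metric=metric
    )


def contrast_vector(
    cb: CrossBasisMatrix,
    x_high: float,
    x_low: float,
    lag_subset=None,
) -> np.ndarray:
    """Coefficient-space vector v for the contrast x_high vs x_low.

    ``v @ beta`` is the (cumulative, if ``lag_subset`` is None) effect of
    moving exposure from x_low to x_high at the selected lags.  Contrasts are
    differences of basis rows, hence independent of any centering constant.
    Values outside the boundary range trigger :class:`ExtrapolationWarning`
    and use the natural (linear) extension.
    """
    b0, b1 = cb.var_spec.boundary
    for x in (x_high, x_low):
        if x < b0 - 1e-12 or x > b1 + 1e-12:
            warnings.warn(
                f"exposure value {x} outside basis boundary range ({b0}, {b1}); "
                "using the natural linear extension",
                ExtrapolationWarning,
                stacklevel=2,
            )
    r_diff = cb.var_basis([x_high])[0] - cb.var_basis([x_low])[0]
    C = cb.lag_basis()
    if lag_subset is None:
        c_sum = C.sum(axis=0)
    else:
        idx = np.atleast_1d(np.asarray(lag_subset, dtype=int))
        if np.any(idx < 0) or np.any(idx >= cb.lags.size):
            raise ValueError("lag_subset outside 0..L-1")
        c_sum = C[idx].sum(axis=0)
    return np.outer(r_diff, c_sum).ravel()
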