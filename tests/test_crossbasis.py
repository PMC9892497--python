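"""Natural cubic spline bases, the tensor-product crossbasis, and contrasts."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import runaq as rq
from runaq.crossbasis import ExtrapolationWarning, contrast_vector


def ns_spec(df, **kw):
    return rq.SplineSpec(df=df, **kw)


class TestNaturalCubicBasis:
    @pytest.mark.parametrize("df", [1, 2, 3, 4, 5])
    def test_column_count_equals_df(self, df):
        spec = ns_spec(df, boundary=(0.0, 1.0))
        B = rq.natural_cubic_basis(np.linspace(0, 1, 7), spec)
        assert B.shape == (7, df)

    @pytest.mark.parametrize("intercept", [False, True])
    def test_linear_beyond_boundary_knots(self, intercept):
        spec = ns_spec(5, boundary=(0.0, 1.0), intercept=intercept)
        left = np.linspace(-3.0, -0.5, 40)
        right = np.linspace(1.5, 4.0, 40)
        for pts in (left, right):
            B = rq.natural_cubic_basis(pts, spec)
            second = np.diff(B, n=2, axis=0)
            assert np.max(np.abs(second)) < 1e-8

    def test_c2_continuity_across_knots(self):
        spec = ns_spec(4, boundary=(0.0, 1.0))
        x = np.linspace(0, 1, 20001)
        B = rq.natural_cubic_basis(x, spec)
        d2 = np.diff(B, n=2, axis=0) / (x[1] - x[0]) ** 2
        # second derivative of a C² function has no jumps on a fine grid
        assert np.max(np.abs(np.diff(d2, axis=0))) < 1e-2

    def test_linear_function_in_span(self):
        # least-squares projection of f(x) = x onto intercept + basis is exact
        x = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        B = rq.natural_cubic_basis(x, ns_spec(4, boundary=(0.0, 1.0)))
        design = np.column_stack([np.ones_like(x), B])
        coefs, *_ = np.linalg.lstsq(design, x, rcond=None)
        assert design @ coefs == pytest.approx(x, abs=1e-10)

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            rq.SplineSpec(df=0)
        with pytest.raises(ValueError):
            rq.SplineSpec(df=3, boundary=(1.0, 1.0))
        with pytest.raises(ValueError):
            rq.SplineSpec(df=2, kind="linear")
        with pytest.raises(ValueError):
            rq.natural_cubic_basis([np.nan], ns_spec(3, boundary=(0, 1)))

    def test_log_placement_knots_concentrate_early(self):
        spec = ns_spec(5, placement="log").resolve(np.arange(21.0))
        ks = np.asarray(spec.internal_knots)
        assert np.all(np.diff(ks) > 0)
        assert np.all(np.diff(np.diff(ks)) > 0)  # spacing widens with lag


class TestBuildCrossbasis:
    def test_df5_by_df5_gives_25_columns(self, desk_model):
        cb = rq.build_crossbasis(
            desk_model["exposure"], ns_spec(5), ns_spec(5, intercept=True)
        )
        assert cb.values.shape[1] == 25
        assert len(cb.colnames) == 25

    def test_constant_exposure_row_separability(self):
        c = 6.5
        rng = np.random.default_rng(1)
        X = np.vstack([np.full(21, c), rng.uniform(0, 15, size=(4, 21))])
        vspec, lspec = ns_spec(4), ns_spec(3, intercept=True)
        cb = rq.build_crossbasis(X, vspec, lspec)
        R = cb.var_basis([c])[0]
        C_sums = cb.lag_basis().sum(axis=0)
        expected = np.outer(R, C_sums).ravel()
        assert cb.values[0] == pytest.approx(expected, abs=1e-9)

    def test_identity_bases_collapse_to_moving_sum(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(1, 20, size=(15, 21))
        cb = rq.build_crossbasis(
            X,
            rq.SplineSpec(df=1, kind="linear"),
            rq.SplineSpec(df=1, kind="const"),
        )
        assert cb.values.shape == (15, 1)
        assert cb.values[:, 0] == pytest.approx(X.sum(axis=1))

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_single_row_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 10, size=21)
        x[rng.integers(21)] = 10.0  # ensure a non-degenerate range
        x[rng.integers(21)] = 0.0
        vspec = ns_spec(int(rng.integers(2, 5)))
        lspec = ns_spec(int(rng.integers(2, 5)), intercept=True)
        cb = rq.build_crossbasis(x[None, :], vspec, lspec)
        R = cb.var_basis(x)
        C = cb.lag_basis()
        expected = np.zeros(vspec.df * lspec.df)
        col = 0
        for j in range(vspec.df):
            for k in range(lspec.df):
                expected[col] = sum(R[l, j] * C[l, k] for l in range(21))
                col += 1
        assert cb.values[0] == pytest.approx(expected, rel=1e-10, abs=1e-10)

    def test_metadata_roundtrip_reproduces_basis(self, desk_model):
        cb = rq.build_crossbasis(
            desk_model["exposure"], ns_spec(4), ns_spec(4, intercept=True)
        )
        meta = json.loads(json.dumps(cb.metadata()))
        vspec = rq.SplineSpec.from_dict(meta["var_spec"])
        lspec = rq.SplineSpec.from_dict(meta["lag_spec"])
        cb2 = rq.build_crossbasis(desk_model["exposure"], vspec, lspec)
        assert np.array_equal(cb.values, cb2.values)


@pytest.fixture(scope="module")
def cb(desk_model):
    return rq.build_crossbasis(
        desk_model["exposure"], ns_spec(5), ns_spec(5, intercept=True)
    )


class TestContrastVector:

    def test_zero_for_equal_endpoints(self, cb):
        assert np.all(contrast_vector(cb, 8.0, 8.0) == 0.0)

    def test_single_lag_vectors_sum_to_all_lag_vector(self, cb):
        total = contrast_vector(cb, 10.0, 5.0)
        parts = sum(
            contrast_vector(cb, 10.0, 5.0, lag_subset=[l]) for l in range(21)
        )
        assert parts == pytest.approx(total, abs=1e-10)

    def test_linear_limit_closed_form(self):
        X = np.random.default_rng(3).uniform(0, 10, size=(10, 21))
        cb = rq.build_crossbasis(
            X, rq.SplineSpec(df=1, kind="linear"), rq.SplineSpec(df=1, kind="const")
        )
        v = contrast_vector(cb, 9.0, 4.0)
        assert v == pytest.approx([21 * (9.0 - 4.0)])

    def test_extrapolation_warns(self, cb):
        hi = cb.var_spec.boundary[1]
        with pytest.warns(ExtrapolationWarning):
            contrast_vector(cb, hi + 5.0, hi - 1.0)

    def test_translation_invariance_with_linear_basis(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 10, size=(30, 21))
        beta = rng.normal(size=21)

        def effect(Xm, x1, x0):
            cb = rq.build_crossbasis(
                Xm,
                rq.SplineSpec(df=1, kind="linear"),
                rq.SplineSpec(df=21, intercept=True),
            )
            # project a fixed per-lag profile into the basis to get coefficients
            C = cb.lag_basis()
            theta, *_ = np.linalg.lstsq(C, beta, rcond=None)
            return contrast_vector(cb, x1, x0) @ theta

        shift = 100.0
        assert effect(X, 8.0, 3.0) == pytest.approx(
            effect(X + shift, 8.0 + shift, 3.0 + shift), rel=1e-6
        )
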