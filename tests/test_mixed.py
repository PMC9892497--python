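"""Crossed random-intercepts ML fit, stepwise AIC, and crossbasis selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import runaq as rq
from runaq.mixed import (
    RankDeficiencyError,
    backward_stepwise_aic,
    select_crossbasis_form,
)


def direct_loglik(y, X, fit, race, uni):
    """Brute-force joint multivariate-normal log-density with the explicit
    n × n covariance sigma2*I + sigma2_race*ZrZr' + sigma2_uni*ZuZu'."""
    race_codes = pd.factorize(race)[0]
    uni_codes = pd.factorize(uni)[0]
    Zr = np.eye(race_codes.max() + 1)[race_codes]
    Zu = np.eye(uni_codes.max() + 1)[uni_codes]
    V = (
        fit.sigma2_resid * np.eye(len(y))
        + fit.sigma2_race * Zr @ Zr.T
        + fit.sigma2_university * Zu @ Zu.T
    )
    mu = X.to_numpy() @ fit.params.to_numpy()
    return stats.multivariate_normal.logpdf(y, mu, V)


def small_grouped_data(seed, n=28, n_race=2, n_uni=2):
    rng = np.random.default_rng(seed)
    race = rng.integers(0, n_race, n)
    uni = rng.integers(0, n_uni, n)
    X = pd.DataFrame({"const": np.ones(n), "x": rng.normal(size=n)})
    y = (
        2.0
        + 0.5 * X["x"].to_numpy()
        + rng.normal(0, 1.5, n_race)[race]
        + rng.normal(0, 1.0, n_uni)[uni]
        + rng.normal(size=n)
    )
    return y, X, race, uni


class TestFitLmm:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_loglik_matches_brute_force_mvn(self, seed):
        y, X, race, uni = small_grouped_data(seed)
        fit = rq.fit_lmm(y, X, race, uni)
        assert fit.loglik == pytest.approx(
            direct_loglik(y, X, fit, race, uni), abs=1e-6
        )

    def test_matches_statsmodels_crossed_ml(self):
        import statsmodels.formula.api as smf

        y, X, race, uni = small_grouped_data(7, n=60, n_race=5, n_uni=3)
        fit = rq.fit_lmm(y, X, race, uni)
        df = pd.DataFrame(
            {"y": y, "x": X["x"], "race": race, "uni": uni, "g": 1}
        )
        sm_fit = smf.mixedlm(
            "y ~ x",
            df,
            groups="g",
            vc_formula={"race": "0 + C(race)", "uni": "0 + C(uni)"},
        ).fit(reml=False)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-4)
        assert fit.params.to_numpy() == pytest.approx(
            sm_fit.fe_params.to_numpy(), abs=1e-4
        )

    def test_zero_variance_limit_matches_ols(self):
        rng = np.random.default_rng(11)
        n = 2000
        X = pd.DataFrame({"const": np.ones(n), "x": rng.normal(size=n)})
        y = 1.0 + 2.0 * X["x"].to_numpy() + rng.normal(size=n)
        fit = rq.fit_lmm(y, X, rng.integers(0, 40, n), rng.integers(0, 10, n))
        ols = np.linalg.lstsq(X.to_numpy(), y, rcond=None)[0]
        assert np.max(np.abs(fit.params.to_numpy() - ols) / np.abs(ols)) < 1e-4

    def test_parameter_recovery_within_3se(self):
        hits = total = 0
        true = np.array([5.0, 1.5, -2.0])
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            n = 600
            race = rng.integers(0, 30, n)
            uni = rng.integers(0, 12, n)
            X = pd.DataFrame(
                {
                    "const": np.ones(n),
                    "a": rng.normal(size=n),
                    "b": rng.normal(size=n),
                }
            )
            y = (
                X.to_numpy() @ true
                + rng.normal(0, 2.0, 30)[race]
                + rng.normal(0, 1.5, 12)[uni]
                + rng.normal(0, 3.0, n)
            )
            fit = rq.fit_lmm(y, X, race, uni)
            se = fit.se().to_numpy()
            hits += int(np.all(np.abs(fit.params.to_numpy() - true) <= 3 * se))
            total += 1
        assert hits / total >= 0.9

    def test_aic_identity(self, desk_fit):
        fit, _ = desk_fit
        assert fit.aic == 2 * fit.n_params - 2 * fit.loglik
        assert fit.n_params == len(fit.params) + 3

    def test_covariance_symmetric_psd(self, desk_fit):
        fit, _ = desk_fit
        C = fit.cov.to_numpy()
        assert np.allclose(C, C.T)
        eig = np.linalg.eigvalsh(C)
        assert eig.min() > -1e-12 * eig.max()

    def test_affine_rescaling_equivariance(self):
        y, X, race, uni = small_grouped_data(13, n=80, n_race=6, n_uni=3)
        fit = rq.fit_lmm(y, X, race, uni)
        X2 = X.copy()
        X2["x"] = X["x"] * 10.0
        fit2 = rq.fit_lmm(y, X2, race, uni)
        assert fit2.params["x"] == pytest.approx(fit.params["x"] / 10.0, rel=1e-4)
        assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-6)

    def test_rank_deficiency_names_columns(self):
        y, X, race, uni = small_grouped_data(17)
        X = X.copy()
        X["x_dup"] = X["x"]
        with pytest.raises(RankDeficiencyError, match="x_dup"):
            rq.fit_lmm(y, X, race, uni)


def selection_data(seed, n=220, noise_col=True):
    rng = np.random.default_rng(seed)
    race = rng.integers(0, 20, n)
    uni = rng.integers(0, 8, n)
    X = pd.DataFrame(
        {
            "const": np.ones(n),
            "a": rng.normal(size=n),
            "b": rng.normal(size=n),
            "noise": rng.normal(size=n),
        }
    )
    y = (
        3.0
        + 2.0 * X["a"].to_numpy()
        - 1.5 * X["b"].to_numpy()
        + rng.normal(0, 1.0, 20)[race]
        + rng.normal(0, 1.0, 8)[uni]
        + rng.normal(size=n)
    )
    terms = {"a": ["a"], "b": ["b"]}
    if noise_col:
        terms["noise"] = ["noise"]
    return y, X, race, uni, terms


class TestBackwardStepwise:
    def test_noise_covariate_usually_removed(self):
        # AIC drops a true-zero covariate iff its LR statistic < 2,
        # i.e. with probability P(chi2_1 < 2) ~ 0.84
        removed = 0
        for seed in range(30):
            y, X, race, uni, terms = selection_data(seed)
            sel = backward_stepwise_aic(y, X, race, uni, terms)
            assert "a" in sel.selected and "b" in sel.selected
            removed += "noise" in sel.dropped
        assert removed / 30 >= 0.7

    def test_all_strong_covariates_retained(self):
        y, X, race, uni, terms = selection_data(3, noise_col=False)
        sel = backward_stepwise_aic(y, X, race, uni, terms)
        assert sorted(sel.selected) == ["a", "b"]
        assert sel.dropped == []

    def test_aic_trace_non_increasing(self):
        y, X, race, uni, terms = selection_data(5)
        sel = backward_stepwise_aic(y, X, race, uni, terms)
        aics = sel.trace["aic"].to_numpy()
        assert np.all(np.diff(aics) <= 0)

    def test_deterministic(self):
        y, X, race, uni, terms = selection_data(9)
        s1 = backward_stepwise_aic(y, X, race, uni, terms)
        s2 = backward_stepwise_aic(y, X, race, uni, terms)
        assert s1.selected == s2.selected
        assert s1.trace.equals(s2.trace)


class TestCrossbasisSelection:
    def test_single_candidate_trivial(self, desk_model):
        cand = [(rq.SplineSpec(df=3), rq.SplineSpec(df=3, intercept=True))]
        (vs, ls), table = select_crossbasis_form(
            desk_model["y"],
            desk_model["X"],
            desk_model["exposure"],
            desk_model["race"],
            desk_model["uni"],
            cand,
        )
        assert (vs.df, ls.df) == (3, 3)
        assert len(table) == 1 and np.isfinite(table["aic"]).all()

    def test_prefers_parsimonious_form_for_smooth_truth(self):
        # truth surface uses a df-3-smooth (linear) exposure response;
        # AIC should rarely pay for the df-5 exposure basis
        chosen_small = 0
        cands = [
            (rq.SplineSpec(df=d), rq.SplineSpec(df=3, intercept=True))
            for d in (3, 4, 5)
        ]
        for seed in range(8):
            study = rq.simulate_study(
                rq.SimulationConfig.desk_scale(), seed=3000 + seed
            )
            races = study.races
            from runaq.pipeline import build_covariate_design

            X = build_covariate_design(races)
            E = rq.build_exposure_matrix(races, study.daily, "pm25", 21)
            (vs, _), _ = select_crossbasis_form(
                races["race_time_s"].to_numpy(),
                X,
                E,
                races["race_id"].to_numpy(),
                races["university_id"].to_numpy(),
                cands,
            )
            chosen_small += vs.df <= 4
        assert chosen_small >= 5

    def test_tie_break_and_table_shape(self, desk_model):
        cands = [
            (rq.SplineSpec(df=3), rq.SplineSpec(df=3, intercept=True)),
            (rq.SplineSpec(df=4), rq.SplineSpec(df=3, intercept=True)),
        ]
        (_, _), table = select_crossbasis_form(
            desk_model["y"],
            desk_model["X"],
            desk_model["exposure"],
            desk_model["race"],
            desk_model["uni"],
            cands,
        )
        assert list(table.columns) == [
            "var_df", "var_placement", "lag_df", "lag_placement",
            "n_basis_cols", "aic", "error",
        ]
        assert table["aic"].notna().all()
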