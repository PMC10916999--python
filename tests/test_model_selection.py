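"""GLM engine, AICc, subset enumeration, family selection, IRRs, pseudo-R2."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from tapcog.keystroke_io import EDUCATION_LEVELS
from tapcog.model_selection import (
    FittedModel,
    ModelSpec,
    ModelTable,
    RankDeficientError,
    adjusted_pseudo_r2,
    aicc,
    build_design,
    dredge_subsets,
    evaluate_hypothesis,
    fit_glm,
    incident_rate_ratios,
    select_family,
)
from tests.conftest import random_covariate_frame


@pytest.fixture(scope="module")
def nb_frame():
    """Covariates + 4 synthetic features with a known NB2 data-generating process."""
    rng = np.random.default_rng(42)
    n = 400
    df = random_covariate_frame(rng, n)
    for j in range(4):
        df[f"f{j}"] = rng.normal(0.0, 1.0, n)
    eta = (
        1.2
        + 0.015 * (df["age_years"] - 66)
        + 0.02 * df["hads_depression"]
        - 0.30 * df["f0"]
        + 0.20 * df["f1"]
    )
    mu = np.exp(eta)
    theta = 1.5
    df["paltea6"] = rng.poisson(rng.gamma(theta, mu / theta))
    return df


class TestAicc:
    def test_closed_form(self):
        assert aicc(-100.0, 3, 50) == pytest.approx(206 + 24 / 46, rel=1e-12)

    def test_limit_equals_aic(self):
        aic = -2 * (-100.0) + 2 * 3
        assert aicc(-100.0, 3, 10**9) == pytest.approx(aic, abs=1e-4)

    def test_k_zero_equals_aic(self):
        assert aicc(-50.0, 0, 10) == 100.0

    def test_small_n_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            aicc(-10.0, 5, 6)


class TestFitGlm:
    def test_intercept_only_poisson_analytic(self):
        df = pd.DataFrame({"paltea6": [3, 3, 3, 3]})
        fm = fit_glm(
            ModelSpec("paltea6", (), "poisson", include_covariates=False), df
        )
        assert fm.params["const"] == pytest.approx(math.log(3.0), abs=1e-8)
        expected_ll = 4 * (3 * math.log(3) - 3 - math.log(6))
        assert fm.loglik == pytest.approx(expected_ll, abs=1e-8)
        assert fm.k == 1

    def test_poisson_matches_statsmodels(self, nb_frame):
        spec = ModelSpec("paltea6", ("f0", "f1"), "poisson")
        fm = fit_glm(spec, nb_frame)
        X, _ = build_design(nb_frame, ("f0", "f1"))
        res = sm.GLM(nb_frame["paltea6"].to_numpy(float), X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fm.params.to_numpy(), res.params, atol=1e-6)
        assert fm.loglik == pytest.approx(res.llf, abs=1e-6)
        np.testing.assert_allclose(fm.bse.to_numpy(), res.bse, rtol=1e-4)

    def test_negbin_matches_statsmodels(self, nb_frame):
        spec = ModelSpec("paltea6", ("f0", "f1"), "negative_binomial")
        fm = fit_glm(spec, nb_frame)
        X, _ = build_design(nb_frame, ("f0", "f1"))
        res = sm.NegativeBinomial(nb_frame["paltea6"].to_numpy(float), X).fit(
            disp=0, maxiter=200
        )
        assert fm.loglik == pytest.approx(res.llf, abs=5e-4)
        np.testing.assert_allclose(fm.params.to_numpy(), res.params[:-1], atol=2e-3)
        assert fm.theta == pytest.approx(1.0 / res.params[-1], rel=5e-3)
        # k: intercept + 9 covariate terms + 2 features + dispersion
        assert fm.k == fm.k_mean + 1

    def test_negbin_recovers_known_coefficients(self, nb_frame):
        fm = fit_glm(ModelSpec("paltea6", ("f0", "f1"), "negative_binomial"), nb_frame)
        for name, truth in [("f0", -0.30), ("f1", 0.20)]:
            assert abs(fm.params[name] - truth) < 3 * fm.bse[name]

    def test_gaussian_equals_ols(self, nb_frame):
        fm = fit_glm(ModelSpec("paltea6", ("f0",), "gaussian"), nb_frame)
        X, _ = build_design(nb_frame, ("f0",))
        res = sm.OLS(nb_frame["paltea6"].to_numpy(float), X).fit()
        np.testing.assert_allclose(fm.params.to_numpy(), res.params, atol=1e-8)
        assert fm.loglik == pytest.approx(res.llf, abs=1e-6)
        assert fm.k == X.shape[1] + 1  # sigma^2 is estimated too

    def test_rank_deficient_design_names_columns(self, nb_frame):
        df = nb_frame.copy()
        df["f_dup"] = df["f0"]
        with pytest.raises(RankDeficientError) as err:
            fit_glm(ModelSpec("paltea6", ("f0", "f_dup"), "poisson"), df)
        assert {"f0", "f_dup"} & set(err.value.columns)

    def test_missing_values_rejected(self, nb_frame):
        df = nb_frame.copy()
        df.loc[df.index[0], "f0"] = np.nan
        with pytest.raises(ValueError, match="missing values"):
            fit_glm(ModelSpec("paltea6", ("f0",), "poisson"), df)


class TestDredge:
    def test_exhaustive_enumeration_and_balance(self, nb_frame):
        feats = ["f0", "f1", "f2"]
        table = dredge_subsets("paltea6", feats, nb_frame, family="poisson")
        assert len(table.table) == 8
        for f in feats:
            n_with = sum(f in combo for combo in table.table["features"])
            assert n_with == 4

    def test_ranking_matches_independent_statsmodels_refits(self, nb_frame):
        feats = ["f0", "f1", "f2"]
        table = dredge_subsets("paltea6", feats, nb_frame, family="poisson")
        oracle = {}
        for r in range(4):
            for combo in itertools.combinations(feats, r):
                X, _ = build_design(nb_frame, combo)
                res = sm.GLM(
                    nb_frame["paltea6"].to_numpy(float), X, family=sm.families.Poisson()
                ).fit()
                k = X.shape[1]
                oracle[tuple(sorted(combo))] = aicc(res.llf, k, len(nb_frame))
        mine = {c: a for c, a in zip(table.table["features"], table.table["aicc"])}
        assert set(mine) == set(oracle)
        for combo in oracle:
            assert mine[combo] == pytest.approx(oracle[combo], abs=1e-5)
        assert list(table.table["features"]) == sorted(oracle, key=oracle.get)

    def test_delta_monotone_and_null_row_present(self, nb_frame):
        table = dredge_subsets("paltea6", ["f0", "f1"], nb_frame, family="negative_binomial")
        deltas = table.table["delta_aicc"].to_numpy()
        assert deltas[0] == 0.0
        assert (np.diff(deltas) >= -1e-12).all()
        assert table.table["is_null"].sum() == 1
        assert () in set(table.table["features"])

    def test_strong_effect_excludes_null_from_equivalence(self, nb_frame):
        table = dredge_subsets(
            "paltea6", ["f0", "f1", "f2", "f3"], nb_frame, family="negative_binomial"
        )
        decision = evaluate_hypothesis(table)
        assert decision.improvement
        assert "f0" in decision.best_features
        assert decision.null_delta_aicc > 2

    def test_cap_enforced(self, nb_frame):
        with pytest.raises(ValueError, match="cap"):
            dredge_subsets("paltea6", ["f0", "f1", "f2"], nb_frame, max_features=2)


class TestEvaluateHypothesis:
    def _table_with_null_delta(self, delta):
        rows = pd.DataFrame(
            {
                "rank": [1, 2],
                "features": [("f0",), ()],
                "n_features": [1, 0],
                "k": [3, 2],
                "loglik": [-10.0, -10.0 - delta / 2],
                "aicc": [100.0, 100.0 + delta],
                "converged": [True, True],
                "pseudo_r2_adj": [0.1, 0.0],
                "is_null": [False, True],
                "delta_aicc": [0.0, delta],
                "equivalent": [True, delta < 2],
            }
        )
        spec = ModelSpec("paltea6", ("f0",), "poisson")
        best = FittedModel(
            spec=spec,
            params=pd.Series([0.0], index=["const"]),
            bse=pd.Series([1.0], index=["const"]),
            loglik=-10.0,
            n=100,
            k=3,
            k_mean=3,
            deviance=1.0,
            converged=True,
        )
        return ModelTable(
            outcome="paltea6",
            family="poisson",
            candidate_features=("f0",),
            table=rows,
            models={("f0",): best, (): best},
            baseline=best,
        )

    def test_boundary_value_below_two_is_equivalence(self):
        decision = evaluate_hypothesis(self._table_with_null_delta(1.9))
        assert not decision.improvement

    def test_above_two_is_improvement(self):
        decision = evaluate_hypothesis(self._table_with_null_delta(2.1))
        assert decision.improvement

    def test_null_being_best_gives_zero_delta(self, nb_frame):
        rng = np.random.default_rng(0)
        df = nb_frame.copy()
        df["noise"] = rng.normal(size=len(df))
        df["pure"] = rng.poisson(3.0, len(df))
        table = dredge_subsets("pure", ["noise"], df, family="poisson")
        d = evaluate_hypothesis(table)
        assert not d.improvement
        assert d.null_delta_aicc < 2


class TestSelectFamily:
    def test_overdispersed_prefers_negative_binomial(self, nb_frame):
        choice = select_family("paltea6", nb_frame)
        assert choice.family == "negative_binomial"
        assert choice.aicc_negbin < choice.aicc_poisson - 2

    def test_equidispersed_retains_poisson(self, nb_frame):
        rng = np.random.default_rng(1)
        df = nb_frame.copy()
        mu = np.exp(1.3 + 0.01 * (df["age_years"] - 66))
        df["paltea6"] = rng.poisson(mu)
        choice = select_family("paltea6", df)
        assert choice.family == "poisson"

    def test_degenerate_outcome_falls_back_to_gaussian(self, covariate_frame_factory):
        rng = np.random.default_rng(0)
        df = covariate_frame_factory(rng, 240)
        y = rng.poisson(4.0, len(df))
        y[df["sex"].to_numpy() == "male"] = 0  # perfect separation
        df["swmbe6"] = y
        choice = select_family("swmbe6", df)
        assert choice.family == "gaussian"
        assert "did not converge" in choice.fallback_reason


class TestIncidentRateRatios:
    def test_irr_is_exp_of_every_coefficient(self, nb_frame):
        fm = fit_glm(ModelSpec("paltea6", (), "poisson"), nb_frame)
        irr = incident_rate_ratios(fm)
        assert np.allclose(irr["irr"], np.exp(fm.params))
        zero_like = fm.params[fm.params.abs() < 1e-12]
        assert np.allclose(np.exp(zero_like), 1.0)

    def test_known_coefficient_maps_through_exp(self):
        spec = ModelSpec("y", (), "poisson", include_covariates=False)
        fm = FittedModel(
            spec=spec,
            params=pd.Series([math.log(0.8)], index=["x"]),
            bse=pd.Series([0.1], index=["x"]),
            loglik=-1.0,
            n=50,
            k=1,
            k_mean=1,
            deviance=1.0,
            converged=True,
        )
        irr = incident_rate_ratios(fm)
        assert irr.loc["x", "irr"] == pytest.approx(0.8, rel=1e-12)
        assert irr.loc["x", "irr_low"] < 0.8 < irr.loc["x", "irr_high"]

    def test_gaussian_family_is_an_error(self, nb_frame):
        fm = fit_glm(ModelSpec("paltea6", (), "gaussian"), nb_frame)
        with pytest.raises(ValueError, match="undefined"):
            incident_rate_ratios(fm)


class TestAdjustedPseudoR2:
    def test_null_model_scores_zero(self, nb_frame):
        null = fit_glm(ModelSpec("paltea6", (), "negative_binomial"), nb_frame)
        base = fit_glm(
            ModelSpec("paltea6", (), "negative_binomial", include_covariates=False),
            nb_frame,
        )
        assert adjusted_pseudo_r2(base, base) == 0.0
        assert adjusted_pseudo_r2(null, base) >= 0.0

    def test_gaussian_reduces_to_classical_adjusted_r2(self, nb_frame):
        fm = fit_glm(ModelSpec("paltea6", ("f0", "f1"), "gaussian"), nb_frame)
        X, _ = build_design(nb_frame, ("f0", "f1"))
        res = sm.OLS(nb_frame["paltea6"].to_numpy(float), X).fit()
        assert adjusted_pseudo_r2(fm) == pytest.approx(res.rsquared_adj, rel=1e-9)

    def test_better_fit_scores_higher(self, nb_frame):
        weak = fit_glm(ModelSpec("paltea6", (), "negative_binomial"), nb_frame)
        strong = fit_glm(
            ModelSpec("paltea6", ("f0", "f1"), "negative_binomial"), nb_frame
        )
        assert adjusted_pseudo_r2(strong) > adjusted_pseudo_r2(weak)
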