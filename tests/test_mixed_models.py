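"""Transforms, collinearity, information criteria, mixed-model machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dissimscale.errors import DataValidationError
from dissimscale.experiments import (
    CORE_SPEC,
    _simulate_lmm_data,
    null_slope_pvalues,
    ols_reduction_check,
)
from dissimscale.mixed_models import (
    LMMFit,
    ModelSpec,
    aicc,
    apply_transform,
    bic,
    collinearity_screen,
    drop_collinear,
    fit_lmm,
    origin_contrasts,
    r2_components,
    select_model,
    transform_response,
)


class TestTransforms:
    def test_response_examples(self):
        assert transform_response([0.0])[0] == 0.0
        assert transform_response([np.e - 1])[0] == pytest.approx(1.0)
        assert transform_response([99.0])[0] == pytest.approx(np.log(100), abs=1e-6)

    def test_response_negative_rejected(self):
        with pytest.raises(DataValidationError):
            transform_response([-0.1])

    def test_zscore_example_and_idempotence(self):
        z = apply_transform(pd.Series([2.0, 4.0], name="x"), "z")
        assert z.tolist() == pytest.approx([-0.7071067811865476, 0.7071067811865476])
        again = apply_transform(z, "z")
        assert np.allclose(z, again, atol=1e-8)

    def test_identity(self):
        s = pd.Series([1.0, 2.0], name="x")
        assert apply_transform(s, "identity").equals(s)

    def test_log_of_nonpositive_names_variable(self):
        with pytest.raises(DataValidationError, match="soil_n"):
            apply_transform(pd.Series([1.0, 0.0], name="soil_n"), "log")


class TestInformationCriteria:
    def test_aicc_closed_form(self):
        # -2(-50) + 2*3 + 2*3*4/(10-3-1) = 106 + 4 = 110
        assert aicc(-50.0, 3, 10) == pytest.approx(110.0)

    def test_bic_closed_form(self):
        assert bic(-50.0, 3, 100) == pytest.approx(100 + 3 * np.log(100), abs=1e-4)
        assert bic(-50.0, 3, 100) == pytest.approx(113.8155, abs=1e-3)

    def test_aicc_approaches_aic(self):
        aic = -2 * (-50.0) + 2 * 3
        assert abs(aicc(-50.0, 3, 10**6) - aic) < 0.01

    def test_aicc_undefined_for_tiny_n(self):
        with pytest.raises(DataValidationError):
            aicc(-50.0, 3, 4)


class TestR2:
    def test_formula_case(self):
        assert r2_components(1.0, 1.0, 2.0) == pytest.approx((0.25, 0.50))

    def test_zero_random_variance(self):
        m, c = r2_components(1.0, 0.0, 1.0)
        assert m == c == pytest.approx(0.5)

    def test_zero_fixed_variance(self):
        m, c = r2_components(0.0, 1.0, 1.0)
        assert m == 0.0 and c == pytest.approx(0.5)


class TestCollinearity:
    def test_orthogonal_predictors_unit_vif(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        rep = collinearity_screen(pd.DataFrame({"x1": x1, "x2": x2}))
        assert rep.vif["x1"] == pytest.approx(1.0, abs=1e-10)
        assert rep.vif["x2"] == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_predictor_infinite_vif(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        rep = collinearity_screen(pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)}))
        assert np.isinf(rep.vif["a"]) and np.isinf(rep.vif["b"])
        assert ("a", "b") in [(p[0], p[1]) for p in rep.flagged_pairs]

    def test_vif_matches_correlation_formula(self):
        # construct x2 with empirical correlation exactly 0.99 to x1
        rng = np.random.default_rng(1)
        x1 = rng.normal(size=200)
        u = rng.normal(size=200)
        u -= u @ x1 / (x1 @ x1) * x1  # orthogonalize
        x1s = (x1 - x1.mean()) / x1.std()
        us = (u - u.mean()) / u.std()
        r = 0.99
        x2 = r * x1s + np.sqrt(1 - r**2) * us
        rep = collinearity_screen(pd.DataFrame({"x1": x1s, "x2": x2}))
        r_emp = np.corrcoef(x1s, x2)[0, 1]
        assert rep.vif["x1"] == pytest.approx(1 / (1 - r_emp**2), rel=1e-9)
        assert 40 < rep.vif["x1"] < 60  # near-duplicate predictor at r ~ 0.99

    def test_drop_collinear_removes_later_listed(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        X = pd.DataFrame({"keep": x, "dup": x + 1e-9 * rng.normal(size=100),
                          "other": rng.normal(size=100)})
        kept, _ = drop_collinear(X, protected=("keep",))
        assert kept == ["keep", "other"]


def make_fake_fit(params, cov, interactions=("phylo_dist",)):
    names = list(params)
    p = pd.Series(params)
    cov_fe = pd.DataFrame(cov, index=names, columns=names)
    spec = ModelSpec("m", ("phylo_dist", "ranked_multi"), tuple(interactions))
    return LMMFit(
        spec=spec, scale="site", reml=True, params=p,
        bse=pd.Series(np.sqrt(np.diag(cov_fe)), index=names), cov_fe=cov_fe,
        vcomp={"species": 0.1}, sigma2=1.0, llf=-10.0, n=100, var_fixed=0.5,
        converged=True,
    )


class TestOriginContrasts:
    def test_slope_combination(self):
        # base slope 1.0, interaction -0.4 -> introduced slope 0.6
        names = ["Intercept", "phylo_dist", "ranked_multi", "introduced",
                 "phylo_dist_x_introduced"]
        params = dict(zip(names, [0.0, 1.0, 0.2, 0.1, -0.4]))
        cov = np.diag([0.01] * 5)
        tab = origin_contrasts(make_fake_fit(params, cov)).set_index("predictor")
        assert tab.loc["phylo_dist", "slope_native"] == pytest.approx(1.0)
        assert tab.loc["phylo_dist", "slope_introduced"] == pytest.approx(0.6)
        assert tab.loc["phylo_dist", "difference"] == pytest.approx(-0.4)
        # SE of the sum with zero covariance
        assert tab.loc["phylo_dist", "se_introduced"] == pytest.approx(np.sqrt(0.02))

    def test_zero_interaction_identical_slopes(self):
        names = ["Intercept", "phylo_dist", "ranked_multi", "introduced",
                 "phylo_dist_x_introduced"]
        params = dict(zip(names, [0.0, 1.0, 0.2, 0.1, 0.0]))
        cov = np.diag([1e-8] * 5)
        tab = origin_contrasts(make_fake_fit(params, cov)).set_index("predictor")
        assert tab.loc["phylo_dist", "slope_native"] == tab.loc["phylo_dist", "slope_introduced"]
        assert tab.loc["phylo_dist", "p_difference"] == pytest.approx(1.0)

    def test_uninteracted_predictor_reports_common_slope(self):
        names = ["Intercept", "phylo_dist", "ranked_multi", "introduced",
                 "phylo_dist_x_introduced"]
        params = dict(zip(names, [0.0, 1.0, 0.2, 0.1, -0.4]))
        tab = origin_contrasts(make_fake_fit(params, np.diag([0.01] * 5))).set_index("predictor")
        row = tab.loc["ranked_multi"]
        assert not row.interacted
        assert row.slope_native == row.slope_introduced == pytest.approx(0.2)


class TestFitLmm:
    def test_reduces_to_ols_without_random_variance(self):
        assert ols_reduction_check(seed=0) < 1e-3

    def test_single_level_factors_collapse_to_exact_ols(self):
        import statsmodels.api as sm

        data = _simulate_lmm_data(7, n=300)
        data["species"] = "only"
        data["year"] = 2000
        data["transect_id"] = "t1"
        fit = fit_lmm(data, CORE_SPEC, scale="site")
        assert fit.method == "ols" and fit.vcomp == {}
        X = sm.add_constant(data[["phylo_dist", "ranked_multi"]], has_constant="add")
        ols = sm.OLS(data["y"].to_numpy(), X).fit()
        assert np.allclose(fit.params.to_numpy(), np.asarray(ols.params), atol=1e-10)

    def test_row_permutation_invariance(self):
        data = _simulate_lmm_data(3, n=400)
        fit1 = fit_lmm(data, CORE_SPEC, scale="site")
        fit2 = fit_lmm(data.sample(frac=1.0, random_state=9), CORE_SPEC, scale="site")
        assert np.allclose(fit1.params, fit2.params, atol=1e-6)

    def test_recovers_variance_components(self):
        data = _simulate_lmm_data(11, n=3000, sd_species=0.8, sd_year=0.0,
                                  sd_transect=0.0, sd_resid=0.5)
        fit = fit_lmm(data, CORE_SPEC, scale="site")
        assert fit.vcomp["species"] == pytest.approx(0.64, rel=0.5)
        assert fit.sigma2 == pytest.approx(0.25, rel=0.2)

    def test_conditional_r2_at_least_marginal(self):
        data = _simulate_lmm_data(5, n=800)
        fit = fit_lmm(data, CORE_SPEC, scale="site")
        r2m, r2c = fit.r2()
        assert 0.0 <= r2m <= r2c <= 1.0

    def test_spec_requires_core_terms(self):
        with pytest.raises(DataValidationError):
            ModelSpec("bad", ("soil_n",))

    def test_null_pvalues_uniform(self):
        """Wald p-values under a zero-effect null pass a KS uniformity test."""
        p = null_slope_pvalues(n_sims=200, seed=123)
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestSelection:
    def test_single_candidate(self):
        data = _simulate_lmm_data(21, n=500)
        data["cover"] = np.expm1(np.clip(data.pop("y"), 0, 4))
        data["origin_binary"] = "native"
        data["field"] = "F1"
        data["transect"] = data["transect_id"]
        sel = select_model(data, [CORE_SPEC], scale="site")
        assert sel.winner.name == "core"

    def test_identical_candidates_deterministic_tie(self):
        data = _simulate_lmm_data(22, n=500)
        data["cover"] = np.expm1(np.clip(data.pop("y"), 0, 4))
        data["origin_binary"] = "native"
        data["field"] = "F1"
        data["transect"] = data["transect_id"]
        twin_a = ModelSpec("twin_a", CORE_SPEC.fixed)
        twin_b = ModelSpec("twin_b", CORE_SPEC.fixed)
        sel = select_model(data, [twin_a, twin_b], scale="site")
        assert sel.winner.name == "twin_a"  # stable sort, equal criteria

    def test_generating_model_usually_wins(self):
        """The structure that generated the data beats an underspecified
        rival in most replicates."""
        wins = 0
        rich = ModelSpec("rich", CORE_SPEC.fixed, interactions=("phylo_dist",))
        for seed in range(10):
            data = _simulate_lmm_data(100 + seed, n=800, beta=(1.0, 0.5, -0.3))
            rng = np.random.default_rng(seed)
            intro = rng.random(len(data)) < 0.3
            data["origin_binary"] = np.where(intro, "introduced", "native")
            # add a real origin interaction on phylo_dist
            data["y"] = data["y"] + 0.5 * data["phylo_dist"] * intro
            data["cover"] = np.expm1(np.clip(data.pop("y"), 0, 5))
            data["field"] = "F1"
            data["transect"] = data["transect_id"]
            sel = select_model(data, [CORE_SPEC, rich], scale="site")
            wins += sel.winner.name == "rich"
        assert wins >= 7
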