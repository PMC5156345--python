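"""Statistical machinery: fits, offsets, pseudo-R2, selection, diagnostics."""

import warnings

import numpy as np
import pandas as pd
import pytest

from sealdive.models import (DiveModel, ModelSpec, orthopoly,
                             residual_acf_report, standardize_covariates,
                             thin_every_k, vif_screen)
from sealdive.simulate import simulate_covariate_table


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def nb_table(seed, n=1000, beta=(0.4, -0.3), theta=2.0, intercept=0.5):
    return simulate_covariate_table(
        n, 5, dict(intercept=intercept, beta=list(beta), theta=theta), "nb", seed)


class TestTablePrep:
    def test_standardize_and_back_transform(self, rng):
        df = pd.DataFrame({"a": rng.normal(5, 2, 200), "b": rng.normal(0, 1, 200)})
        out, scaling = standardize_covariates(df, ["a", "b"])
        mu, sd = scaling["a"]
        np.testing.assert_allclose(out["a"] * sd + mu, df["a"], atol=1e-12)
        assert out["a"].std(ddof=1) == pytest.approx(1.0)
        assert out["a"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_standardized_slope_identity(self, rng):
        import statsmodels.api as sm
        x = rng.normal(10, 3, 500)
        y = 2.0 * x + rng.normal(0, 1, 500)
        df = pd.DataFrame({"x": x, "y": y})
        raw = sm.OLS(y, sm.add_constant(x)).fit().params[1]
        std, scaling = standardize_covariates(df, ["x"])
        scaled = sm.OLS(y, sm.add_constant(std["x"])).fit().params[1]
        assert scaled == pytest.approx(raw * scaling["x"][1], rel=1e-9)

    def test_zero_variance_dropped(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="zero variance"):
            out, scaling = standardize_covariates(df, ["a", "b"])
        assert "a" not in out.columns and "a" not in scaling

    def test_thinning(self):
        df = pd.DataFrame({"individual_id": ["i1"] * 100, "v": range(100)})
        assert len(thin_every_k(df, 10)) == 10
        assert thin_every_k(df, 1).equals(df)

    def test_thinning_decorrelates_ar1(self, rng):
        n = 3000
        e = np.empty(n)
        e[0] = rng.standard_normal()
        for t in range(1, n):
            e[t] = 0.6 * e[t - 1] + rng.standard_normal()
        df = pd.DataFrame({"individual_id": ["i1"] * n, "r": e})
        thinned = thin_every_k(df, 10)["r"].to_numpy()
        ac1 = np.corrcoef(thinned[1:], thinned[:-1])[0, 1]
        assert abs(ac1) < 0.1

    def test_vif_orthogonal_and_collinear(self, rng):
        x = rng.standard_normal((400, 3))
        df = pd.DataFrame(x, columns=["a", "b", "c"])
        v = vif_screen(df, ["a", "b", "c"])
        assert (v < 1.2).all()
        df["d"] = df["a"]
        with pytest.warns(UserWarning, match="VIF"):
            v2 = vif_screen(df, ["a", "b", "d"])
        assert np.isinf(v2["a"]) and np.isinf(v2["d"])
        df["e"] = df["a"] + 0.05 * rng.standard_normal(400)
        with pytest.warns(UserWarning, match="VIF"):
            v3 = vif_screen(df, ["a", "b", "e"])
        assert v3["e"] > 5


class TestNegBin:
    def test_parameter_recovery_single_fit(self):
        tbl, _ = nb_table(seed=21)
        res = DiveModel(ModelSpec("negbin", "y", {"x1": 1, "x2": 1},
                                  offset="bottom_duration_min"), tbl).fit()
        assert res.params["x1"] == pytest.approx(0.4, abs=3 * res.bse["x1"])
        assert res.params["x2"] == pytest.approx(-0.3, abs=3 * res.bse["x2"])
        assert res.theta == pytest.approx(2.0, rel=0.35)

    def test_offset_contract_intercept_shift(self):
        tbl, _ = nb_table(seed=22)
        spec = ModelSpec("negbin", "y", {"x1": 1, "x2": 1},
                         offset="bottom_duration_min")
        r1 = DiveModel(spec, tbl).fit()
        tbl2 = tbl.copy()
        tbl2["bottom_duration_min"] *= 2.0
        r2 = DiveModel(spec, tbl2).fit()
        assert r2.params["Intercept"] - r1.params["Intercept"] == pytest.approx(
            -np.log(2.0), abs=1e-6)
        # fitted rates are invariant
        np.testing.assert_allclose(r1.fitted_mean, r2.fitted_mean, rtol=1e-5)

    def test_poisson_nesting_for_large_theta(self):
        import statsmodels.api as sm
        tbl, _ = nb_table(seed=23, theta=1e12)
        spec = ModelSpec("negbin", "y", {"x1": 1, "x2": 1},
                         offset="bottom_duration_min")
        res = DiveModel(spec, tbl).fit()
        X = np.column_stack([np.ones(len(tbl)), tbl.x1, tbl.x2])
        pois = sm.GLM(tbl.y.to_numpy(), X, family=sm.families.Poisson(),
                      offset=np.log(tbl.bottom_duration_min)).fit()
        assert res.theta > 50
        assert abs(res.llf - pois.llf) < 1.0

    def test_non_integer_response_rejected(self):
        tbl, _ = nb_table(seed=24)
        tbl["y"] = tbl["y"] + 0.5
        with pytest.raises(ValueError, match="integer"):
            DiveModel(ModelSpec("negbin", "y", {"x1": 1},
                                offset="bottom_duration_min"), tbl)

    def test_aic_identity(self):
        tbl, _ = nb_table(seed=25)
        res = DiveModel(ModelSpec("negbin", "y", {"x1": 1, "x2": 1},
                                  offset="bottom_duration_min"), tbl).fit()
        k = len(res.params) + 1          # + dispersion
        assert res.aic == pytest.approx(2 * k - 2 * res.llf, rel=1e-9)


class TestDevianceExplained:
    def test_null_model_explains_nothing(self):
        tbl, _ = nb_table(seed=26, beta=(0.0, 0.0))
        res = DiveModel(ModelSpec("negbin", "y", {},
                                  offset="bottom_duration_min"), tbl).fit()
        assert abs(res.deviance_explained()) < 0.5

    def test_strong_signal_high_d2(self):
        tbl, _ = nb_table(seed=27, beta=(1.5, -1.2), theta=50.0)
        res = DiveModel(ModelSpec("negbin", "y", {"x1": 1, "x2": 1},
                                  offset="bottom_duration_min"), tbl).fit()
        assert res.deviance_explained() > 50.0

    def test_noise_covariate_adds_little(self):
        tbl, _ = nb_table(seed=28)
        rng = np.random.default_rng(0)
        tbl["x3"] = rng.standard_normal(len(tbl))
        base = DiveModel(ModelSpec("negbin", "y", {"x1": 1, "x2": 1},
                                   offset="bottom_duration_min"), tbl).fit()
        noisy = DiveModel(ModelSpec("negbin", "y", {"x1": 1, "x2": 1, "x3": 1},
                                    offset="bottom_duration_min"), tbl).fit()
        gain = noisy.deviance_explained() - base.deviance_explained()
        assert 0 <= gain < 1.0

    def test_per_covariate_nde(self):
        tbl, _ = nb_table(seed=29, beta=(1.0, 0.0), theta=20.0)
        model = DiveModel(ModelSpec("negbin", "y", {"x1": 1, "x2": 1},
                                    offset="bottom_duration_min"), tbl)
        res = model.fit()
        nde = model.per_covariate_nde(res)
        assert nde["x1"] > 10.0
        assert abs(nde["x2"]) < 1.0
        assert (nde > -1e-6).all()


class TestMixedModel:
    def test_variance_components_recovered(self):
        tbl, _ = simulate_covariate_table(
            1000, 20, dict(intercept=1.0, beta=[0.5, -0.2], sd_individual=1.0,
                           sd_residual=2.0), "lmm", seed=31)
        res = DiveModel(ModelSpec("lmm", "y", {"x1": 1, "x2": 1},
                                  groups="individual_id"), tbl).fit(reml=True)
        assert res.params["x1"] == pytest.approx(0.5, abs=3 * res.bse["x1"])
        assert np.sqrt(res.sigma2_random) == pytest.approx(1.0, rel=0.6)
        assert np.sqrt(res.sigma2_residual) == pytest.approx(2.0, rel=0.1)

    def test_zero_random_variance_degenerate(self):
        tbl, _ = simulate_covariate_table(
            800, 10, dict(intercept=0.0, beta=[0.3], sd_individual=0.0,
                          sd_residual=1.0), "lmm", seed=32)
        res = DiveModel(ModelSpec("lmm", "y", {"x1": 1},
                                  groups="individual_id"), tbl).fit(reml=True)
        assert res.sigma2_random < 0.05
        r2m, r2c = res.nakagawa_r2()
        assert r2c - r2m < 0.05

    def test_nakagawa_partition(self):
        # variance split sigma2_f : sigma2_u : sigma2_e of 1 : 1 : 2
        tbl, _ = simulate_covariate_table(
            6000, 30, dict(intercept=0.0, beta=[1.0], sd_individual=1.0,
                           sd_residual=np.sqrt(2.0)), "lmm", seed=33)
        res = DiveModel(ModelSpec("lmm", "y", {"x1": 1},
                                  groups="individual_id"), tbl).fit(reml=True)
        r2m, r2c = res.nakagawa_r2()
        assert r2m == pytest.approx(0.25, abs=0.05)
        assert r2c == pytest.approx(0.50, abs=0.07)

    def test_interaction_slopes_recovered(self, rng):
        # distinct depth slopes for descent vs ascent, as in the transit model
        n = 600
        depth = rng.standard_normal(n)
        eff = rng.standard_normal(n)
        phase = np.where(np.arange(n) % 2 == 0, "descent", "ascent")
        asc = (phase == "ascent").astype(float)
        y = (200 + 50 * depth + 30 * asc + 20 * asc * depth + 5 * eff
             + rng.normal(0, 10, n))
        tbl = pd.DataFrame({"duration_s": y, "max_depth_m": depth,
                            "mean_effort": eff, "phase": phase,
                            "individual_id": np.repeat([f"i{j}" for j in range(6)],
                                                       n // 6)})
        res = DiveModel.transit_duration(tbl).fit(reml=True)
        # factor levels sort alphabetically: 'descent' is the indicator level,
        # so the main depth slope is the ascent one (50 + 20) and the
        # interaction carries descent - ascent = -20
        assert res.params["max_depth_m"] == pytest.approx(70, abs=2)
        assert res.params["phase:max_depth_m"] == pytest.approx(-20, abs=3)


class TestBetaRegression:
    def test_mean_and_precision_recovered(self):
        tbl, _ = simulate_covariate_table(
            1500, 5, dict(intercept=0.3, beta=[0.5, -0.4],
                          precision_intercept=2.0, precision_beta=[0.5, 0.0]),
            "beta", seed=34)
        res = DiveModel(ModelSpec("beta", "y", {"x1": 1, "x2": 1}), tbl).fit()
        assert res.params["x1"] == pytest.approx(0.5, abs=0.1)
        assert res.precision_params["Intercept"] == pytest.approx(2.0, abs=0.3)
        assert res.precision_params["x1"] == pytest.approx(0.5, abs=0.3)
        assert abs(res.precision_params["x2"]) < 0.3

    def test_logit_zero_gives_half(self):
        tbl, _ = simulate_covariate_table(
            1000, 5, dict(intercept=0.0, beta=[0.0],
                          precision_intercept=2.5, precision_beta=[0.0]),
            "beta", seed=35)
        res = DiveModel(ModelSpec("beta", "y", {"x1": 1}), tbl).fit()
        assert res.fitted_mean.mean() == pytest.approx(0.5, abs=0.05)

    def test_boundary_response_rejected(self):
        tbl, _ = simulate_covariate_table(
            100, 5, dict(intercept=0.0, beta=[0.0],
                         precision_intercept=2.0, precision_beta=[0.0]),
            "beta", seed=36)
        tbl.loc[0, "y"] = 1.0
        with pytest.raises(ValueError, match="dive-efficiency|strictly"):
            DiveModel(ModelSpec("beta", "y", {"x1": 1}), tbl)


class TestPearson2:
    def test_perfect_fit_is_one(self, rng):
        x = rng.standard_normal(300)
        tbl = pd.DataFrame({"x1": x, "y": 2.0 + 3.0 * x})
        res = DiveModel(ModelSpec("gaussian", "y", {"x1": 1}), tbl).fit()
        assert res.pearson2() == pytest.approx(1.0, abs=1e-9)

    def test_unrelated_predictor_near_zero(self, rng):
        tbl = pd.DataFrame({"x1": rng.standard_normal(2000),
                            "y": rng.standard_normal(2000)})
        res = DiveModel(ModelSpec("gaussian", "y", {"x1": 1}), tbl).fit()
        assert res.pearson2() < 0.01

    def test_bounded_on_count_fit(self):
        tbl, _ = nb_table(seed=37)
        res = DiveModel(ModelSpec("negbin", "y", {"x1": 1, "x2": 1},
                                  offset="bottom_duration_min"), tbl).fit()
        assert 0.0 <= res.pearson2() <= 1.0


def selection_table(seed, n=500, quad=False):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 6))
    y = 1.0 * x[:, 0] - 0.8 * x[:, 1] + 0.6 * x[:, 2] + rng.standard_normal(n)
    if quad:
        y = y + 0.6 * (x[:, 2] ** 2 - 1.0)
    df = pd.DataFrame(x, columns=[f"x{i + 1}" for i in range(6)])
    df["y"] = y
    return df


class TestSelection:
    def test_single_strong_covariate_retained(self):
        rng = np.random.default_rng(41)
        df = pd.DataFrame({"x1": rng.standard_normal(300)})
        df["y"] = 2.0 * df.x1 + rng.standard_normal(300)
        model = DiveModel(ModelSpec("gaussian", "y", {"x1": 1}), df)
        assert "x1" in model.stepwise_aic().covariates

    def test_strong_support_recovered(self):
        df = selection_table(seed=42)
        spec = ModelSpec("gaussian", "y", {f"x{i + 1}": 1 for i in range(6)})
        sel = DiveModel(spec, df).stepwise_aic()
        assert {"x1", "x2", "x3"} <= set(sel.covariates)

    def test_quadratic_degree_escalated(self):
        # AIC keeps a spurious extra degree with ~16% probability per
        # replicate, so judge over several seeds: the quadratic is always
        # found and the exact degree dominates
        degrees = []
        for seed in range(20):
            df = selection_table(seed=200 + seed, quad=True)
            model = DiveModel(ModelSpec("gaussian", "y",
                                        {f"x{i + 1}": 1 for i in range(6)}), df)
            sel = model.polynomial_escalation(model.stepwise_aic())
            degrees.append(sel.covariates["x3"])
        assert all(d >= 2 for d in degrees)
        assert np.mean([d == 2 for d in degrees]) >= 0.6

    def test_degree_never_exceeds_cap(self, rng):
        x = rng.standard_normal(400)
        y = np.sin(3 * x) + 0.1 * rng.standard_normal(400)   # very non-linear
        df = pd.DataFrame({"x1": x, "y": y})
        model = DiveModel(ModelSpec("gaussian", "y", {"x1": 1}), df)
        sel = model.polynomial_escalation(model.spec)
        assert sel.covariates["x1"] <= 4

    def test_orthopoly_columns_uncorrelated(self, rng):
        p = orthopoly(rng.standard_normal(500), 3)
        c = np.corrcoef(p.T)
        assert np.max(np.abs(c - np.eye(3))) < 1e-9


class TestResidualAcf:
    def test_white_noise_within_bounds(self, rng):
        resid = rng.standard_normal(400 * 5)
        ind = np.repeat([f"i{k}" for k in range(5)], 400)
        rep = residual_acf_report(resid, ind)
        lag1 = rep[rep.lag == 1]
        assert (lag1.acf.abs() < lag1.bound).mean() >= 0.8
        assert (rep[rep.lag == 0].acf == 1.0).all()

    def test_ar1_detected(self, rng):
        n = 800
        e = np.empty(n)
        e[0] = rng.standard_normal()
        for t in range(1, n):
            e[t] = 0.8 * e[t - 1] + rng.standard_normal()
        rep = residual_acf_report(e, np.array(["i1"] * n))
        assert rep[rep.lag == 1].acf.iloc[0] > 0.5
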