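"""Weighted multivariable/univariable regression core and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import make_triplet, wls_oracle
from gwasmvr.regression import (InsufficientDataError, SingularDesignError,
                                WeightedEffectRegression, bonferroni_threshold,
                                fit_weighted_mvr, fit_weighted_uvr,
                                likelihood_ratio_test, variance_inflation)
from gwasmvr.selection import align_to_risk

EXP = ("E1", "E2")


class TestFitWeightedMvr:
    def test_exact_linear_relation_recovered(self, rng):
        t = make_triplet(rng, 40, theta=(2.0, -3.0), noise=0.0)
        res = fit_weighted_mvr(t, EXP, "OUT")
        assert res.intercept["estimate"] == pytest.approx(0.0, abs=1e-12)
        assert res.slope("E1")["estimate"] == pytest.approx(2.0, rel=1e-12)
        assert res.slope("E2")["estimate"] == pytest.approx(-3.0, rel=1e-12)
        assert res.df_resid == 37

    def test_null_outcome_gives_zero_fit(self, rng):
        t = make_triplet(rng, 30)
        t["beta_OUT"] = 0.0
        res = fit_weighted_mvr(t, EXP, "OUT")
        assert np.allclose(res.estimates["estimate"], 0.0)
        assert res.r2_weighted == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        worst = 0.0
        for _ in range(100):
            t = make_triplet(rng, 50, theta=(rng.normal(), rng.normal()),
                             noise=abs(rng.normal()) + 0.05)
            res = fit_weighted_mvr(t, EXP, "OUT")
            X = t[["beta_E1", "beta_E2"]].to_numpy()
            o = wls_oracle(X, t["beta_OUT"].to_numpy(),
                           t["se_OUT"].to_numpy() ** -2.0)
            for col, key in (("estimate", "params"), ("se", "se"),
                             ("t", "t"), ("p", "p")):
                got = res.estimates[col].to_numpy()
                want = o[key]
                worst = max(worst, float(np.max(
                    np.abs(got - want) / np.maximum(np.abs(want), 1e-300))))
            worst = max(worst, abs(res.loglik - o["loglik"])
                        / max(abs(o["loglik"]), 1e-300))
        assert worst < 1e-10

    def test_matches_statsmodels_wls(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        t = make_triplet(rng, 60)
        res = fit_weighted_mvr(t, EXP, "OUT")
        X = sm.add_constant(t[["beta_E1", "beta_E2"]].to_numpy())
        fit = sm.WLS(t["beta_OUT"].to_numpy(), X,
                     weights=t["se_OUT"].to_numpy() ** -2.0).fit()
        np.testing.assert_allclose(res.estimates["estimate"], fit.params, rtol=1e-10)
        np.testing.assert_allclose(res.estimates["se"], fit.bse, rtol=1e-10)
        np.testing.assert_allclose(res.estimates["p"], fit.pvalues, rtol=1e-8)
        assert res.loglik == pytest.approx(fit.llf, rel=1e-10)
        assert res.r2_weighted == pytest.approx(fit.rsquared, rel=1e-10)

    def test_weight_scale_invariance(self, rng):
        t = make_triplet(rng, 40)
        res1 = fit_weighted_mvr(t, EXP, "OUT")
        t2 = t.copy()
        t2["se_OUT"] *= 7.3  # rescales all weights by one constant
        res2 = fit_weighted_mvr(t2, EXP, "OUT")
        np.testing.assert_allclose(res1.estimates["estimate"],
                                   res2.estimates["estimate"], rtol=1e-12)
        np.testing.assert_allclose(res1.estimates["t"], res2.estimates["t"],
                                   rtol=1e-10)

    def test_global_sign_flip_keeps_slopes(self, rng):
        t = make_triplet(rng, 40)
        flipped = t.copy()
        for c in ("beta_E1", "beta_E2", "beta_OUT"):
            flipped[c] = -flipped[c]
        r1 = fit_weighted_mvr(t, EXP, "OUT")
        r2 = fit_weighted_mvr(flipped, EXP, "OUT")
        for e in EXP:
            assert r1.slope(e)["estimate"] == pytest.approx(
                r2.slope(e)["estimate"], rel=1e-12)
        assert r1.intercept["estimate"] == pytest.approx(
            -r2.intercept["estimate"], rel=1e-12)

    def test_reported_allele_invariance_via_orientation(self, rng):
        """Risk-allele orientation makes fits independent of how alleles were
        originally reported: flip any subset of rows, re-orient, same fit."""
        t = make_triplet(rng, 60)
        scrambled = t.copy()
        mask = rng.random(60) < 0.5
        for c in ("beta_E1", "beta_E2", "beta_OUT"):
            scrambled.loc[mask, c] = -scrambled.loc[mask, c]
        r1 = fit_weighted_mvr(align_to_risk(t, "E1"), EXP, "OUT")
        r2 = fit_weighted_mvr(align_to_risk(scrambled, "E1"), EXP, "OUT")
        pd.testing.assert_frame_equal(r1.estimates, r2.estimates)

    def test_insufficient_rows(self, rng):
        with pytest.raises(InsufficientDataError):
            fit_weighted_mvr(make_triplet(rng, 3), EXP, "OUT")

    def test_singular_design_named(self, rng):
        t = make_triplet(rng, 30)
        t["beta_E2"] = 2.0 * t["beta_E1"]
        with pytest.raises(SingularDesignError, match="collinear"):
            fit_weighted_mvr(t, EXP, "OUT")


class TestFitWeightedUvr:
    def test_exact_slope(self, rng):
        t = make_triplet(rng, 30)
        t["beta_OUT"] = 0.5 * t["beta_E1"]
        res = fit_weighted_uvr(t, "E1", "OUT")
        assert res.slope("E1")["estimate"] == pytest.approx(0.5, rel=1e-12)
        assert res.intercept["estimate"] == pytest.approx(0.0, abs=1e-12)
        assert res.df_resid == 28

    def test_null_outcome(self, rng):
        t = make_triplet(rng, 30)
        t["beta_OUT"] = 0.0
        assert fit_weighted_uvr(t, "E1", "OUT").slope("E1")["estimate"] == 0.0

    def test_equals_mvr_slope_when_exposures_w_orthogonal(self, rng):
        t = make_triplet(rng, 50)
        w = t["se_OUT"].to_numpy() ** -2.0
        x1 = t["beta_E1"].to_numpy()
        x2 = t["beta_E2"].to_numpy()
        # make x2 w-orthogonal to span{1, x1}: orthogonalize the basis first
        x1c = x1 - np.sum(w * x1) / np.sum(w)
        x2 = x2 - np.sum(w * x2) / np.sum(w)
        x2 = x2 - (np.sum(w * x2 * x1c) / np.sum(w * x1c * x1c)) * x1c
        assert abs(np.sum(w * x1c * x2)) < 1e-8
        t["beta_E2"] = x2
        uvr = fit_weighted_uvr(t, "E1", "OUT")
        mvr = fit_weighted_mvr(t, EXP, "OUT")
        assert uvr.slope("E1")["estimate"] == pytest.approx(
            mvr.slope("E1")["estimate"], rel=1e-6)


class TestLikelihoodRatio:
    def test_identical_fit_gives_zero(self, rng):
        t = make_triplet(rng, 30)
        full = fit_weighted_mvr(t, EXP, "OUT")
        assert likelihood_ratio_test(full, full) == (0.0, 1.0)

    def test_statistic_nonnegative_on_random_tables(self, rng):
        for _ in range(100):
            t = make_triplet(rng, int(rng.integers(10, 40)))
            full = fit_weighted_mvr(t, EXP, "OUT")
            red = fit_weighted_uvr(t, "E1", "OUT")
            stat, p = likelihood_ratio_test(red, full)
            assert stat >= 0.0
            assert 0.0 <= p <= 1.0

    def test_null_added_exposure_p_uniform(self):
        """Adding an exposure with zero true effect: LRT p ~ Uniform(0,1)."""
        rng = np.random.default_rng(314)
        ps = []
        for _ in range(500):
            t = make_triplet(rng, 100, theta=(0.5, 0.0), noise=0.3, rho=0.0)
            full = fit_weighted_mvr(t, EXP, "OUT")
            red = fit_weighted_uvr(t, "E1", "OUT")
            ps.append(likelihood_ratio_test(red, full)[1])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_mismatched_rows_rejected(self, rng):
        t = make_triplet(rng, 30)
        full = fit_weighted_mvr(t, EXP, "OUT")
        red = fit_weighted_uvr(t.iloc[:20], "E1", "OUT")
        with pytest.raises(ValueError):
            likelihood_ratio_test(red, full)


class TestVarianceInflation:
    def test_closed_form_at_weighted_correlation(self, rng):
        n, r = 400, 0.6
        w = rng.uniform(0.5, 2.0, n)
        z1 = rng.normal(size=n)
        z2 = rng.normal(size=n)
        # exact weighted Gram-Schmidt, then mix with weighted correlation r
        ones = np.ones(n)
        for basis in (ones,):
            z1 -= (w @ (z1 * basis)) / (w @ (basis * basis)) * basis
            z2 -= (w @ (z2 * basis)) / (w @ (basis * basis)) * basis
        z2 -= (w @ (z2 * z1)) / (w @ (z1 * z1)) * z1
        z1 /= np.sqrt(w @ z1 ** 2)
        z2 /= np.sqrt(w @ z2 ** 2)
        x2 = r * z1 + np.sqrt(1 - r ** 2) * z2
        t = pd.DataFrame({"beta_E1": z1, "beta_E2": x2})
        vif = variance_inflation(t, EXP, w)
        assert vif["E1"] == pytest.approx(1.0 / (1 - r ** 2), rel=1e-9)
        assert vif["E2"] == pytest.approx(1.5625, rel=1e-9)

    def test_uncorrelated_is_one_and_identical_is_inf(self, rng):
        n = 300
        w = np.ones(n)
        z1 = rng.normal(size=n)
        z2 = rng.normal(size=n)
        ones = np.ones(n)
        for basis in (ones,):
            z1 -= (z1 @ basis) / n * basis
            z2 -= (z2 @ basis) / n * basis
        z2 -= (z2 @ z1) / (z1 @ z1) * z1
        t = pd.DataFrame({"beta_E1": z1, "beta_E2": z2})
        vif = variance_inflation(t, EXP, w)
        assert vif["E1"] == pytest.approx(1.0, rel=1e-9)
        t2 = pd.DataFrame({"beta_E1": z1, "beta_E2": z1})
        vif2 = variance_inflation(t2, EXP, w)
        assert np.isinf(vif2["E1"]) and np.isinf(vif2["E2"])


class TestBonferroni:
    @pytest.mark.parametrize("alpha, n, rounded", [
        (0.05, 22, 0.0023),   # discovery grid: 2 models x 11 thresholds
        (0.05, 4, 0.0125),    # follow-up: 2 models x 2 thresholds
        (0.05, 12, 0.0042),   # disorder specificity analyses
        (0.05, 25, 0.002),    # genetic-correlation analyses
        (0.05, 1, 0.05),
    ])
    def test_reported_thresholds(self, alpha, n, rounded):
        got = bonferroni_threshold(alpha, n)
        assert got.rounded == pytest.approx(rounded, abs=1e-12)
        assert got.exact == pytest.approx(alpha / n, rel=1e-15)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)


class TestSklearnInterface:
    def test_get_set_params_and_clone(self):
        from sklearn.base import clone
        est = WeightedEffectRegression(rcond_min=1e-10)
        assert clone(est).get_params()["rcond_min"] == 1e-10

    def test_fit_predict_roundtrip(self, rng):
        X = rng.normal(size=(50, 2))
        y = 1.0 + X @ np.array([0.5, -0.25]) + 0.01 * rng.normal(size=50)
        est = WeightedEffectRegression().fit(X, y, sample_weight=np.ones(50))
        assert est.coef_.shape == (2,)
        assert np.corrcoef(est.predict(X), y)[0, 1] > 0.99
        assert est.score(X, y) > 0.99
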