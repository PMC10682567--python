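"""GLM estimates, Wald inference, predictions, marginal means, contrasts.

Independent oracles: closed-form maximum-likelihood estimates for
intercept-only and 2x2 designs, derivative-free likelihood maximization
for general fits, the quadratic form x' Sigma x for prediction standard
errors, and the Bonferroni inequality bracketing the single-step adjusted
p values.
"""

import datetime

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special

from exsertia.covariates import DesignMatrix, build_design
from exsertia.inference import (
    FitError,
    fit_glm,
    marginal_means,
    predict_surface,
    tukey_contrasts,
    wald_table,
)
from tests.conftest import GLOBAL_SEED, make_record, present_record


def design_from_arrays(y, X_cols, model="geo_binary", fruit_mean=0.5,
                       species=None):
    X = pd.DataFrame(X_cols, index=range(len(y)))
    X.insert(0, "const", 1.0)
    return DesignMatrix(model=model, response=np.asarray(y, dtype=float),
                        X=X, record_ids=[str(i) for i in range(len(y))],
                        fruit_mean=fruit_mean, species=species)


def neg_loglik(family):
    def binomial(beta, X, y):
        eta = X @ beta
        return -np.sum(y * eta - np.log1p(np.exp(eta)))

    def poisson(beta, X, y):
        eta = X @ beta
        return -np.sum(y * eta - np.exp(eta) - special.gammaln(y + 1))

    return binomial if family == "binomial" else poisson


def brute_force_mle(family, X, y, k):
    res = optimize.minimize(
        neg_loglik(family), np.zeros(k), args=(X, y), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 50_000,
                 "maxfev": 50_000})
    assert res.success
    return res.x


class TestClosedForms:
    def test_binomial_intercept_only_is_log_odds(self):
        y = np.array([1.0] * 25 + [0.0] * 75)
        fit = fit_glm(design_from_arrays(y, {}), family="binomial")
        assert fit.params["const"] == pytest.approx(np.log(25 / 75), abs=1e-8)

    def test_poisson_intercept_only_is_log_mean(self):
        y = np.array([2.0, 3.0, 4.0] * 10)
        fit = fit_glm(design_from_arrays(y, {}), family="poisson")
        assert fit.params["const"] == pytest.approx(np.log(3.0), abs=1e-8)

    def test_two_by_two_slope_is_log_odds_ratio(self):
        # exposed: 10 successes, 40 failures; unexposed: 30 successes, 20 failures
        y = np.array([1.0] * 10 + [0.0] * 40 + [1.0] * 30 + [0.0] * 20)
        x = np.array([1.0] * 50 + [0.0] * 50)
        fit = fit_glm(design_from_arrays(y, {"x": x}), family="binomial")
        assert fit.params["x"] == pytest.approx(
            np.log((10 * 20) / (40 * 30)), abs=1e-8)

    @pytest.mark.parametrize("family", ["binomial", "poisson"])
    def test_irls_matches_derivative_free_oracle(self, family):
        rng = np.random.default_rng(GLOBAL_SEED)
        n = 200
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        eta = 0.3 + 0.8 * x1 - 0.5 * x2
        if family == "binomial":
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        else:
            y = rng.poisson(np.exp(eta * 0.5)).astype(float)
        design = design_from_arrays(y, {"x1": x1, "x2": x2})
        fit = fit_glm(design, family=family)
        oracle = brute_force_mle(family, np.asarray(design.X), y, 3)
        assert np.allclose(fit.params.values, oracle, atol=1e-6)


class TestFitDiagnostics:
    def test_score_identity_binomial(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=150)
        y = (rng.random(150) < 0.3).astype(float)
        fit = fit_glm(design_from_arrays(y, {"x": x}), family="binomial")
        eta = np.asarray([1.0] * 150) * fit.params["const"] + x * fit.params["x"]
        assert np.mean(1 / (1 + np.exp(-eta))) == pytest.approx(
            y.mean(), abs=1e-10)

    def test_score_identity_poisson(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=150)
        y = rng.poisson(2.0, 150).astype(float)
        fit = fit_glm(design_from_arrays(y, {"x": x}), family="poisson")
        mu = np.exp(fit.params["const"] + x * fit.params["x"])
        assert mu.sum() == pytest.approx(y.sum(), rel=1e-8)

    def test_separation_raises_with_guidance(self):
        x = np.array([-2.0, -1.5, -1.0, 1.0, 1.5, 2.0] * 5)
        y = (x > 0).astype(float)
        with pytest.raises(FitError, match="separation"):
            fit_glm(design_from_arrays(y, {"x": x}), family="binomial")

    def test_rank_deficient_design_raises(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(FitError, match="rank"):
            fit_glm(design_from_arrays(y, {"x": x, "x2": 2 * x}),
                    family="binomial")

    def test_invalid_response_codings_raise(self):
        with pytest.raises(FitError):
            fit_glm(design_from_arrays([0.0, 2.0, 1.0], {}), "binomial")
        with pytest.raises(FitError):
            fit_glm(design_from_arrays([0.5, 2.0, 1.0], {}), "poisson")


class TestWaldTable:
    def test_zero_coefficient_has_p_one(self):
        y = np.array([0.0, 1.0] * 50)  # log-odds 0
        fit = fit_glm(design_from_arrays(y, {}), family="binomial")
        table = wald_table(fit)
        assert table.loc["const", "p"] == pytest.approx(1.0, abs=1e-8)

    def test_1_96_se_gives_p_05(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=400)
        y = (rng.random(400) < 1 / (1 + np.exp(-0.3 * x))).astype(float)
        fit = fit_glm(design_from_arrays(y, {"x": x}), family="binomial")
        table = wald_table(fit)
        z = table.loc["x", "beta"] / table.loc["x", "se"]
        assert table.loc["x", "z"] == pytest.approx(z)
        # verify the normal-tail mapping at the conventional threshold
        fit.params["x"] = 1.959963985 * fit.bse["x"]
        assert wald_table(fit).loc["x", "p"] == pytest.approx(0.05, abs=1e-6)

    def test_row_order_follows_design_columns(self):
        rng = np.random.default_rng(7)
        cols = {"a": rng.normal(size=80), "b": rng.normal(size=80)}
        y = (rng.random(80) < 0.4).astype(float)
        fit = fit_glm(design_from_arrays(y, cols), family="binomial")
        assert list(wald_table(fit).index) == ["const", "a", "b"]


def _species_fit(rng, n_per=120, shift=1.2, identical=False):
    records = []
    for j, sp in enumerate(("inflata", "cardinalis", "kalmii")):
        p = 0.3 if identical else 1 / (1 + np.exp(-(-1.0 + shift * j)))
        for i in range(n_per):
            present = rng.random() < p
            maker = present_record if present else make_record
            records.append(maker(
                f"{sp}{i}", species=sp,
                observation_date=datetime.date(2020, 6, 1)
                + datetime.timedelta(days=int(rng.integers(0, 100))),
                fruit_present="yes" if rng.random() < 0.6 else "no"))
    design, params = build_design(records, "species_binary")
    return fit_glm(design), params


class TestPredictionsAndMeans:
    def test_intercept_only_probability_half(self):
        y = np.array([0.0, 1.0] * 40)
        fit = fit_glm(design_from_arrays(y, {}), family="binomial")
        surface = predict_surface(fit, "const", [1.0], params={})
        assert surface["mean"][0] == pytest.approx(0.5, abs=1e-8)
        # bounds are symmetric on the linear predictor scale
        lo, hi = special.logit(surface["lower"][0]), special.logit(surface["upper"][0])
        assert lo + hi == pytest.approx(2 * surface["eta"][0], abs=1e-8)

    def test_poisson_intercept_predicts_mean_count(self):
        y = np.array([1.0, 2.0, 3.0] * 20)
        fit = fit_glm(design_from_arrays(y, {}), family="poisson")
        surface = predict_surface(fit, "const", [1.0], params={})
        assert surface["mean"][0] == pytest.approx(2.0, rel=1e-8)

    def test_se_eta_equals_quadratic_form(self, rng):
        records = []
        for i in range(80):
            maker = present_record if i % 2 else make_record
            records.append(maker(
                f"r{i}", latitude=40 + rng.uniform(-4, 4),
                longitude=-80 + rng.uniform(-5, 5),
                elevation=float(rng.uniform(0, 500)),
                observation_date=datetime.date(2020, 7, 1)
                + datetime.timedelta(days=int(rng.integers(0, 60))),
                fruit_present="yes" if rng.random() < 0.5 else "no"))
        marg = {r.record_id: float(rng.uniform(0, 1)) for r in records}
        design, params = build_design(records, "geo_binary", marg)
        fit = fit_glm(design)
        surface = predict_surface(fit, "z_marginality", [0.0, 0.5, 1.0],
                                  params=params)
        sp = params["z_marginality"]
        for _, row in surface.iterrows():
            x = np.zeros(len(fit.terms))
            x[fit.terms.index("const")] = 1.0
            x[fit.terms.index("fruit")] = fit.fruit_mean
            x[fit.terms.index("z_marginality")] = \
                (row["z_marginality"] - sp.mean) / sp.sd
            se = np.sqrt(x @ fit.cov.values @ x)
            assert row["se_eta"] == pytest.approx(se, abs=1e-12)
            assert row["lower"] < row["mean"] < row["upper"]
            assert 0 < row["lower"] and row["upper"] < 1

    def test_extrapolated_grid_values_are_flagged(self, rng):
        records = []
        for i in range(60):
            maker = present_record if i % 3 else make_record
            records.append(maker(
                f"r{i}", latitude=40 + rng.uniform(0, 2),
                longitude=-80 + rng.uniform(0, 2),
                elevation=float(rng.uniform(100, 200)),
                observation_date=datetime.date(2020, 7, 1)
                + datetime.timedelta(days=int(rng.integers(0, 30))),
                fruit_present="yes" if i % 2 else "no"))
        marg = {r.record_id: float(rng.uniform(0.2, 0.8)) for r in records}
        design, params = build_design(records, "geo_binary", marg)
        fit = fit_glm(design)
        surface = predict_surface(fit, "z_latitude", [41.0, 55.0], params)
        assert not surface["extrapolated"][0]
        assert surface["extrapolated"][1]

    def test_identical_species_have_identical_marginal_means(self, rng):
        fit, params = _species_fit(rng, identical=True)
        means = marginal_means(fit, params)
        assert means["mean"].max() - means["mean"].min() < 0.15
        assert (means["lower"] < means["mean"]).all()
        assert (means["mean"] < means["upper"]).all()

    def test_reference_species_mean_is_linked_intercept_plus_offsets(self, rng):
        fit, params = _species_fit(rng)
        means = marginal_means(fit, params)
        eta_ref = fit.params["const"] + fit.params["fruit"] * fit.fruit_mean
        assert means.loc["inflata", "eta"] == pytest.approx(eta_ref, abs=1e-12)

    def test_means_track_empirical_fractions_in_balanced_design(self, rng):
        fit, _ = _species_fit(rng, n_per=400, shift=1.0)
        means = marginal_means(fit, None)
        assert means.loc["inflata", "mean"] < means.loc["cardinalis", "mean"]
        assert list(means["mean"].sort_values().index) == \
            ["inflata", "cardinalis", "kalmii"]


class TestTukeyContrasts:
    def test_two_groups_adjusted_equals_raw(self, rng):
        records = []
        for sp, p in (("inflata", 0.3), ("kalmii", 0.5)):
            for i in range(150):
                maker = present_record if rng.random() < p else make_record
                records.append(maker(
                    f"{sp}{i}", species=sp,
                    observation_date=datetime.date(2020, 6, 1)
                    + datetime.timedelta(days=int(rng.integers(0, 80))),
                    fruit_present="yes" if rng.random() < 0.6 else "no"))
        design, _ = build_design(records, "species_binary")
        table = tukey_contrasts(fit_glm(design))
        assert len(table) == 1
        assert table["p_adj"].iloc[0] == pytest.approx(
            table["p_raw"].iloc[0], abs=0.002)

    def test_identical_groups_give_null_contrast(self):
        # byte-identical data per species: every contrast is exactly zero
        records = []
        for sp in ("inflata", "kalmii", "spicata"):
            for i in range(60):
                maker = present_record if i % 3 == 0 else make_record
                records.append(maker(
                    f"{sp}{i}", species=sp,
                    observation_date=datetime.date(2020, 6, 1)
                    + datetime.timedelta(days=i),
                    fruit_present="yes" if i % 2 else "no"))
        design, _ = build_design(records, "species_binary")
        table = tukey_contrasts(fit_glm(design))
        assert np.allclose(table["estimate"], 0.0, atol=1e-8)
        assert (table["p_adj"] > 0.99).all()

    def test_bracketed_by_raw_and_bonferroni(self, rng):
        fit, _ = _species_fit(rng)
        mvn = tukey_contrasts(fit, adjust="mvn")
        bonf = tukey_contrasts(fit, adjust="bonferroni")
        m = len(mvn)
        assert (mvn["p_adj"] >= mvn["p_raw"]).all()
        assert (mvn["p_adj"] <=
                np.minimum(1.0, m * mvn["p_raw"]) + 0.01).all()
        assert np.allclose(bonf["p_adj"],
                           np.minimum(1.0, m * bonf["p_raw"]))

    def test_seeded_adjustment_is_reproducible(self, rng):
        fit, _ = _species_fit(rng)
        first = tukey_contrasts(fit, seed=1234)
        second = tukey_contrasts(fit, seed=1234)
        pd.testing.assert_frame_equal(first, second)
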