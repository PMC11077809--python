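import numpy as np
import pandas as pd
import pytest

from amgcap.glm import (
    DesignEncoding,
    FittedGLM,
    ModelSpec,
    build_design,
    fit_glm,
    information_criteria,
    predict,
    pseudo_r2_deviance,
)

from conftest import small_config
from amgcap.simulate import generate_population


def _records(rows):
    df = pd.DataFrame(rows, columns=["sex", "age_years", "amg_code", "cost_eur"])
    df["person_id"] = np.arange(len(df))
    df["area_id"] = "A"
    return df


class TestBuildDesign:
    def test_all_reference_row_activates_intercept_only(self):
        rec = _records([(0, 3, 1, 10.0), (1, 83, 405, 20.0)])
        X, y, enc = build_design(rec)
        row = X.iloc[0]
        assert row["const"] == 1.0
        assert row.drop("const").sum() == 0.0

    def test_banding_83_maps_to_band_80(self):
        rec = _records([(0, 3, 1, 10.0), (1, 83, 405, 20.0)])
        X, _, _ = build_design(rec)
        row = X.iloc[1]
        active = set(row[row != 0].index)
        assert active == {"const", "sex", "age_80", "amg_405"}

    def test_ages_84_and_87_differ_only_in_band_column(self):
        enc = DesignEncoding(age_bands=(0, 80, 85), amg_codes=(1,))
        rec = _records([(0, 84, 1, 1.0), (0, 87, 1, 1.0)])
        X, _, _ = build_design(rec, enc)
        diff = (X.iloc[0] != X.iloc[1])
        assert set(X.columns[diff]) == {"age_80", "age_85"}

    def test_unseen_level_raises_naming_level(self):
        train = _records([(0, 10, 1, 5.0), (0, 20, 101, 5.0)])
        _, _, enc = build_design(train)
        test = _records([(0, 10, 335, 5.0)])
        with pytest.raises(ValueError, match="335"):
            build_design(test, enc)

    def test_column_order_is_deterministic(self):
        rec = _records([(0, 12, 321, 1.0), (1, 7, 101, 2.0), (0, 30, 1, 3.0)])
        X, _, _ = build_design(rec)
        assert list(X.columns) == ["const", "sex", "age_5", "age_10", "age_30",
                                   "amg_101", "amg_321"]


class TestFitGLM:
    def test_gaussian_identity_recovers_exact_line(self):
        X = pd.DataFrame({"const": [1.0, 1, 1], "x": [0.0, 1, 2]})
        y = pd.Series([1.0, 3.0, 5.0])
        m = fit_glm(X, y, ModelSpec("gaussian", "identity"))
        assert np.allclose(m.coefficients, [1.0, 2.0])
        assert m.deviance < 1e-12

    def test_gaussian_identity_equals_ols(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"const": 1.0, "x1": rng.normal(size=200),
                          "x2": rng.normal(size=200)})
        y = pd.Series(2 + X["x1"] - 0.5 * X["x2"] + rng.normal(size=200))
        m = fit_glm(X, y, ModelSpec("gaussian", "identity"))
        beta_ols, *_ = np.linalg.lstsq(np.asarray(X), np.asarray(y), rcond=None)
        assert np.allclose(m.coefficients.to_numpy(), beta_ols, rtol=1e-8)

    def test_gamma_log_zero_noise_recovers_coefficients(self):
        x = np.linspace(-1, 1, 50)
        X = pd.DataFrame({"const": 1.0, "x": x})
        y = pd.Series(np.exp(0.5 + 1.2 * x))
        m = fit_glm(X, y, ModelSpec("gamma", "log"))
        assert np.allclose(m.coefficients, [0.5, 1.2], atol=1e-7)
        assert m.deviance < 1e-8

    def test_gamma_requires_positive_response(self):
        X = pd.DataFrame({"const": [1.0, 1.0]})
        with pytest.raises(ValueError, match="positive"):
            fit_glm(X, pd.Series([1.0, 0.0]), ModelSpec("gamma", "log"))

    def test_rank_deficient_design_raises(self):
        X = pd.DataFrame({"const": [1.0] * 4, "dup": [1.0] * 4})
        with pytest.raises(ValueError, match="rank deficient"):
            fit_glm(X, pd.Series([1.0, 2, 3, 4]), ModelSpec("gaussian", "identity"))

    def test_parameter_recovery_within_3_se(self):
        """Gamma/log fit on generator output recovers each true
        coefficient within 3 standard errors."""
        cfg = small_config(20_000, seed=101)
        rec = generate_population(cfg)
        X, y, enc = build_design(rec)
        m = fit_glm(X, y, ModelSpec("gamma", "log"), enc)
        assert m.converged
        truth = cfg.true_coefficients.reindex(m.coefficients.index)
        z = (m.coefficients - truth).abs() / m.bse
        assert (z < 3).all(), z[z >= 3]

    def test_nested_model_deviance_monotone(self, small_population):
        X, y, _ = build_design(small_population)
        spec = ModelSpec("gamma", "log")
        m_small = fit_glm(X[["const", "sex"]], y, spec)
        m_big = fit_glm(X[["const", "sex", "amg_335"]], y, spec)
        assert m_big.deviance <= m_small.deviance + 1e-8
        assert m_small.null_deviance >= m_small.deviance


class TestPredict:
    def test_log_link_all_reference_row(self):
        rec = _records([(0, 2, 1, 1.0), (1, 3, 1, 2.0), (0, 4, 1, 1.5)])
        X, y, enc = build_design(rec)
        m = fit_glm(X, y, ModelSpec("gamma", "log"), enc)
        m.coefficients[:] = 0.0
        m.coefficients["const"] = 5.731
        out = predict(m, X)
        assert np.isclose(out["mu"].iloc[0], np.exp(5.731))

    def test_identity_link_mu_equals_eta(self, small_population):
        X, y, enc = build_design(small_population)
        m = fit_glm(X, y, ModelSpec("gaussian", "identity"), enc)
        out = predict(m, X)
        assert np.allclose(out["mu"], out["eta"])

    def test_power_half_link_squares_eta(self):
        rng = np.random.default_rng(9)
        x = np.linspace(0, 1, 200)
        X = pd.DataFrame({"const": 1.0, "x": x})
        y = pd.Series((1.0 + 2.0 * x) ** 2 + rng.normal(scale=1e-4, size=200))
        m = fit_glm(X, y, ModelSpec("gaussian", "power_half"))
        out = predict(m, X)
        assert np.allclose(out["mu"], out["eta"] ** 2)
        # eta = 3 -> mu = 9
        probe = pd.DataFrame({"const": [1.0], "x": [1.0]})
        eta = float(predict(m, probe)["eta"].iloc[0])
        assert np.isclose(eta, 3.0, atol=1e-6)
        assert np.isclose(float(predict(m, probe)["mu"].iloc[0]), 9.0, atol=1e-5)

    def test_log_link_predictions_invariant_to_reference_level(
        self, small_population
    ):
        """Relabelling which AMG is the reference level must not change
        fitted means (reparameterisation invariance)."""
        spec = ModelSpec("gamma", "log")
        X, y, enc = build_design(small_population)
        mu_a = predict(fit_glm(X, y, spec, enc), X)["mu"].to_numpy()
        swapped = small_population.copy()
        swapped["amg_code"] = swapped["amg_code"].map(
            lambda c: {1: 321, 321: 1}.get(c, c)
        )
        X2, y2, enc2 = build_design(swapped)
        mu_b = predict(fit_glm(X2, y2, spec, enc2), X2)["mu"].to_numpy()
        assert np.allclose(mu_a, mu_b, rtol=1e-6)


class TestInformationCriteria:
    def test_gaussian_aic_matches_closed_form(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"const": 1.0, "x": rng.normal(size=10)})
        y = pd.Series(1 + X["x"] + rng.normal(size=10))
        m = fit_glm(X, y, ModelSpec("gaussian", "identity"))
        resid = y - predict(m, X)["mu"]
        rss = float((resid**2).sum())
        n, k = 10, 3  # intercept, slope, variance
        aic_closed = n * np.log(rss / n) + 2 * k + n * (1 + np.log(2 * np.pi))
        assert np.isclose(information_criteria(m)["aic"], aic_closed, rtol=1e-10)

    def test_aic_monotone_in_rss_at_equal_k(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=100)
        X = pd.DataFrame({"const": 1.0, "x": x})
        y_good = pd.Series(x + rng.normal(scale=0.1, size=100))
        y_bad = pd.Series(x + rng.normal(scale=2.0, size=100))
        aic_good = information_criteria(
            fit_glm(X, y_good, ModelSpec("gaussian", "identity"))
        )["aic"]
        aic_bad = information_criteria(
            fit_glm(X, y_bad, ModelSpec("gaussian", "identity"))
        )["aic"]
        assert aic_good < aic_bad

    def test_unconverged_model_is_refused(self, small_model):
        import dataclasses

        broken = dataclasses.replace(small_model, converged=False)
        with pytest.raises(RuntimeError, match="converge"):
            information_criteria(broken)


class TestPseudoR2:
    def test_bounds_and_trivial_cases(self, small_model):
        r2 = pseudo_r2_deviance(small_model)
        assert 0.0 < r2 < 1.0
        import dataclasses

        null = dataclasses.replace(small_model, deviance=small_model.null_deviance)
        assert pseudo_r2_deviance(null) == 0.0
        perfect = dataclasses.replace(small_model, deviance=0.0)
        assert pseudo_r2_deviance(perfect) == 1.0


def test_model_json_round_trip(tmp_path, small_model):
    path = tmp_path / "model.json"
    small_model.save(path)
    loaded = FittedGLM.load(path)
    assert loaded.spec == small_model.spec
    assert np.allclose(loaded.coefficients, small_model.coefficients)
    assert loaded.encoding == small_model.encoding
    assert loaded.n == small_model.n and loaded.k == small_model.k
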