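"""Allometric models: registry forms, NLS fitting, evaluation, bootstrap."""

import math

import numpy as np
import pytest

from tlscarbon import (
    FitError,
    MODEL_REGISTRY,
    evaluate_model,
    fit_power_law,
    fit_uk_model,
    parametric_bootstrap,
    predict,
    predict_agb,
)
from tlscarbon.allometry import load_registry, save_registry


UNIT_METRICS = dict(dbh=1.0, dtb=1.0, fdbh=1.0, h=1.0, crown_volume=1.0)


class TestPredict:
    @pytest.mark.parametrize("model_id,expected", [
        ("parks", 10 ** (-0.4147)),              # log10(DBH^2 H) = 0 at unit input
        ("jenkins", math.exp(-2.0336)),          # ln(DBH) = 0 at unit input
        ("sillett2015", 1.95e-3 + 1.78e-4),      # unit inputs sum the coefficients
        ("sillett2019", 1.1588e-3 + 1.0898e-4),
        ("chojnacky", 3.9656e-4 + 1.9583e-3),
    ])
    def test_unit_inputs_isolate_coefficients(self, model_id, expected):
        assert predict(MODEL_REGISTRY[model_id], UNIT_METRICS) == pytest.approx(expected)

    def test_volume_models_convert_to_agb_by_density(self):
        model = MODEL_REGISTRY["parks"]
        v = predict(model, UNIT_METRICS)
        assert predict_agb(model, UNIT_METRICS) == pytest.approx(v * 0.34)
        # AGB models pass through unchanged
        j = MODEL_REGISTRY["jenkins"]
        assert predict_agb(j, UNIT_METRICS) == pytest.approx(predict(j, UNIT_METRICS))

    def test_missing_metric_is_named(self):
        with pytest.raises(ValueError, match="crown_volume"):
            predict(MODEL_REGISTRY["sillett2015"], dict(dtb=1.0, crown_volume=None))

    def test_non_positive_input_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            predict(MODEL_REGISTRY["jenkins"], dict(dbh=0.0))

    @pytest.mark.parametrize("model_id", sorted(MODEL_REGISTRY))
    def test_strictly_increasing_in_each_predictor(self, model_id):
        """Every published form grows with each of its (positive) inputs."""
        model = MODEL_REGISTRY[model_id]
        base = {k: 2.0 for k in UNIT_METRICS}
        y0 = predict(model, base)
        for name in model.inputs:
            bumped = dict(base)
            bumped[name] = 2.5
            assert predict(model, bumped) > y0


class TestPowerLawFit:
    def test_noiseless_exact_recovery(self):
        """A noiseless power law is identified to 1e-6 in both parameters."""
        x = np.linspace(0.3, 2.3, 97)
        y = 3.542 * x**1.956
        fit = fit_power_law(x, y)
        assert fit.a == pytest.approx(3.542, abs=1e-6)
        assert fit.b == pytest.approx(1.956, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert abs(fit.bias_pct) < 1e-8
        # refitting reproduces the coefficients exactly
        refit = fit_power_law(x, y)
        assert (refit.a, refit.b) == (fit.a, fit.b)

    def test_noisy_recovery_median_error_below_5pct(self):
        """5% Gaussian noise, n=97: median |a_hat - a|/a < 5% over 200 seeds."""
        x = np.linspace(0.3, 2.3, 97)
        a, b = 3.542, 1.956
        y0 = a * x**b
        sd = 0.05 * y0.mean()
        errs_a, errs_b = [], []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            fit = fit_power_law(x, y0 + rng.normal(0, sd, x.size))
            errs_a.append(abs(fit.a - a) / a)
            errs_b.append(abs(fit.b - b) / b)
        assert np.median(errs_a) < 0.05
        assert np.median(errs_b) < 0.05

    def test_degenerate_predictor_variance(self):
        x = np.full(10, 1.5)
        y = np.linspace(1, 2, 10)
        with pytest.raises(FitError, match="variance"):
            fit_power_law(x, y)

    def test_too_few_trees(self):
        with pytest.raises(FitError, match=">= 5"):
            fit_power_law([1, 2, 3], [1, 2, 3])

    def test_uk_forms_use_combined_predictors(self):
        """The DBH-H form regresses AGB on DBH^2*H."""
        rng = np.random.default_rng(3)
        n = 40
        dbh = rng.uniform(0.3, 2.0, n)
        h = rng.uniform(10, 50, n)
        agb = 0.374 * (dbh**2 * h) ** 0.697
        trees = [
            (dict(dbh=d, dtb=d * 0.9, h=hh, crown_volume=100.0), a)
            for d, hh, a in zip(dbh, h, agb)
        ]
        fit = fit_uk_model("dbh_h", trees)
        assert fit.a == pytest.approx(0.374, abs=1e-6)
        assert fit.b == pytest.approx(0.697, abs=1e-6)
        with pytest.raises(ValueError, match="unknown UK form"):
            fit_uk_model("dbh_cubed", trees)


class TestEvaluateModel:
    def test_identity_prediction(self):
        obs = np.linspace(1.0, 20.0, 10)
        ev = evaluate_model(obs, obs)
        assert ev.gradient == pytest.approx(1.0)
        assert ev.intercept == pytest.approx(0.0, abs=1e-12)
        assert ev.rmse == pytest.approx(0.0, abs=1e-12)
        assert ev.r2 == pytest.approx(1.0)

    def test_doubled_prediction(self):
        obs = np.linspace(1.0, 20.0, 10)
        ev = evaluate_model(2 * obs, obs)
        assert ev.gradient == pytest.approx(2.0)
        assert ev.intercept == pytest.approx(0.0, abs=1e-12)
        assert ev.r2 == pytest.approx(1.0)
        assert ev.rmse == pytest.approx(float(np.sqrt(np.mean(obs**2))))

    def test_matches_normal_equations_oracle(self):
        """Ten-point dataset agrees with a hand-rolled OLS solution."""
        rng = np.random.default_rng(8)
        obs = rng.uniform(1, 30, 10)
        pred = 1.3 * obs - 0.7 + rng.normal(0, 1.5, 10)
        X = np.column_stack([obs, np.ones(10)])
        slope, intercept = np.linalg.solve(X.T @ X, X.T @ pred)
        ev = evaluate_model(pred, obs)
        assert ev.gradient == pytest.approx(slope, rel=1e-10)
        assert ev.intercept == pytest.approx(intercept, rel=1e-10)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate_model([1, 2, 3], [1, 2])


class TestBootstrap:
    @pytest.fixture
    def noisy_fit(self):
        rng = np.random.default_rng(12)
        x = np.linspace(0.3, 2.3, 60)
        y = 3.5 * x**2.0 + rng.normal(0, 0.3, x.size)
        return fit_power_law(x, y)

    def test_zero_residual_envelope_collapses(self):
        x = np.linspace(0.5, 2.0, 30)
        fit = fit_power_law(x, 2.0 * x**1.5)
        env = parametric_bootstrap(fit, n_boot=25, seed=0)
        np.testing.assert_allclose(env.hi, env.lo, atol=1e-6)
        np.testing.assert_allclose(env.hi, fit.predict(env.x_grid), atol=1e-6)

    def test_deterministic_for_fixed_seed(self, noisy_fit):
        e1 = parametric_bootstrap(noisy_fit, n_boot=30, seed=7)
        e2 = parametric_bootstrap(noisy_fit, n_boot=30, seed=7)
        np.testing.assert_array_equal(e1.lo, e2.lo)
        np.testing.assert_array_equal(e1.hi, e2.hi)

    def test_envelope_shrinks_with_sample_size(self):
        """More calibration trees tighten the bootstrap band."""
        a, b, sd = 3.5, 2.0, 0.4
        widths = []
        for n in (30, 300):
            rng = np.random.default_rng(42)
            x = np.linspace(0.3, 2.3, n)
            fit = fit_power_law(x, a * x**b + rng.normal(0, sd, n))
            env = parametric_bootstrap(fit, n_boot=60, seed=1,
                                       x_grid=np.linspace(0.5, 2.0, 20))
            widths.append(float(np.mean(env.p97_5 - env.p2_5)))
        assert widths[1] < widths[0]


def test_registry_round_trip(tmp_path):
    path = tmp_path / "registry.json"
    save_registry(path)
    back = load_registry(path)
    assert set(back) == set(MODEL_REGISTRY)
    assert back["parks"].coefficients == MODEL_REGISTRY["parks"].coefficients
    assert back["uk_dbh"].output == "agb_mg"
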