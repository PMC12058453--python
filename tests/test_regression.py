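"""Collinearity screen, Gaussian GLM, stepwise AIC, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from herdcycles.errors import InvalidParameterError
from herdcycles.regression import (
    backward_stepwise_aic,
    collinearity_screen,
    fit_glm,
    period_amplitude_association,
    residual_diagnostics,
)
from herdcycles.synthetic import generate_regression_benchmark


def _numeric_frame(rng, n=60, k=3):
    return pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(k)})


class TestCollinearityScreen:
    def test_perfect_copy_drops_exactly_one(self):
        rng = np.random.default_rng(0)
        df = _numeric_frame(rng)
        df["x_copy"] = df["x0"]
        kept, flagged = collinearity_screen(df)
        assert len(flagged) == 1 and flagged[0][2] == pytest.approx(1.0)
        assert ("x0" in kept) != ("x_copy" in kept)

    def test_ecotype_function_of_subspecies_dropped_by_priority(self):
        rng = np.random.default_rng(1)
        sub = rng.choice(["a", "b", "c"], 60)
        eco = np.where(sub == "a", "low", "high")  # deterministic function
        df = pd.DataFrame({
            "subspecies": sub,
            "ecotype": eco,
            "ndvi_dhi": rng.normal(size=60),
        })
        kept, flagged = collinearity_screen(df)
        assert "ecotype" not in kept and "subspecies" in kept
        assert any({a, b} == {"subspecies", "ecotype"} for a, b, _ in flagged)

    def test_independent_predictors_untouched(self):
        rng = np.random.default_rng(2)
        df = _numeric_frame(rng, n=500, k=4)
        kept, flagged = collinearity_screen(df)
        assert flagged == [] and len(kept) == 4


class TestFitGLM:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(3)
        df = _numeric_frame(rng, n=30, k=1)
        df["y"] = 2.0 + 3.25 * df["x0"]
        fit = fit_glm(df, "y", ["x0"])
        assert fit.params["x0"] == pytest.approx(3.25, abs=1e-10)
        assert fit.params["Intercept"] == pytest.approx(2.0, abs=1e-10)

    def test_intercept_only_data_slope_near_zero(self):
        rng = np.random.default_rng(4)
        ests = []
        for _ in range(100):
            df = _numeric_frame(rng, n=40, k=1)
            df["y"] = 5.0 + rng.normal(0, 1, 40)
            ests.append(fit_glm(df, "y", ["x0"]).params["x0"])
        assert abs(np.mean(ests)) < 3 / np.sqrt(40 * 100)

    def test_weak_beta_recovery_at_small_n(self):
        # known beta on ndvi at n=19; the estimator is unbiased, so the
        # mean over replicates sits within 2 Monte-Carlo SEs of the truth
        ests = []
        for seed in range(200):
            data, truth = generate_regression_benchmark(
                n=19, betas={"ndvi_dhi": -1.6}, noise_sd=5.0, seed=seed)
            fit = fit_glm(data, "y", ["ndvi_dhi", "winter_tmin"])
            ests.append(fit.params["ndvi_dhi"])
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - (-1.6)) < 2 * mc_se

    def test_rank_deficiency_names_aliased_terms(self):
        rng = np.random.default_rng(5)
        df = _numeric_frame(rng, n=30, k=1)
        df["x_dup"] = df["x0"]
        df["y"] = rng.normal(size=30)
        with pytest.raises(InvalidParameterError, match="aliased"):
            fit_glm(df, "y", ["x0", "x_dup"])

    def test_too_few_rows_rejected(self):
        rng = np.random.default_rng(6)
        df = _numeric_frame(rng, n=4, k=3)
        df["y"] = rng.normal(size=4)
        with pytest.raises(InvalidParameterError, match="n > p"):
            fit_glm(df, "y", ["x0", "x1", "x2"])


class TestStepwise:
    def test_trace_strictly_decreasing(self):
        rng = np.random.default_rng(7)
        df = _numeric_frame(rng, n=50, k=5)
        df["y"] = 1.0 + 2 * df["x0"] + rng.normal(0, 1, 50)
        res = backward_stepwise_aic(fit_glm(df, "y", [f"x{i}" for i in range(5)]))
        aics = [a for _, a in res.aic_trace]
        assert all(b < a for a, b in zip(aics, aics[1:]))

    def test_minimal_model_returned_unchanged(self):
        rng = np.random.default_rng(8)
        df = _numeric_frame(rng, n=80, k=2)
        df["y"] = 3 * df["x0"] - 4 * df["x1"] + rng.normal(0, 0.5, 80)
        res = backward_stepwise_aic(fit_glm(df, "y", ["x0", "x1"]))
        assert sorted(res.terms) == ["x0", "x1"]
        assert len(res.aic_trace) == 1

    def test_null_retention_rate_matches_aic_theory(self):
        # a single pure-noise predictor survives backward AIC iff its
        # likelihood-ratio chi2(1) exceeds 2: P ~ 0.157
        rng = np.random.default_rng(9)
        kept = 0
        reps = 300
        for _ in range(reps):
            df = _numeric_frame(rng, n=100, k=1)
            df["y"] = rng.normal(size=100)
            res = backward_stepwise_aic(fit_glm(df, "y", ["x0"]))
            kept += "x0" in res.terms
        rate = kept / reps
        assert abs(rate - 0.157) < 3 * np.sqrt(0.157 * 0.843 / reps)

    def test_categorical_block_dropped_whole(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({
            "x0": rng.normal(size=80),
            "grp": rng.choice(["a", "b", "c", "d"], 80),
        })
        df["y"] = 2 * df["x0"] + rng.normal(0, 1, 80)
        res = backward_stepwise_aic(fit_glm(df, "y", ["x0", "grp"]))
        assert "x0" in res.terms
        grp_params = [k for k in res.params if "grp" in k]
        assert grp_params == [] or "grp" in res.terms

    def test_selection_invariant_to_column_order(self):
        rng = np.random.default_rng(11)
        df = _numeric_frame(rng, n=60, k=4)
        df["y"] = 2.5 * df["x2"] + rng.normal(0, 1, 60)
        terms = ["x0", "x1", "x2", "x3"]
        a = backward_stepwise_aic(fit_glm(df, "y", terms))
        b = backward_stepwise_aic(fit_glm(df, "y", terms[::-1]))
        assert sorted(a.terms) == sorted(b.terms)
        assert a.aic == pytest.approx(b.aic)

    def test_confidence_interval_coverage_on_known_coefficients(self):
        # full-model 95% CIs over replicates of the benchmark generator
        rng_seeds = range(500)
        hits = 0
        for seed in rng_seeds:
            data, truth = generate_regression_benchmark(
                n=43, betas={"ndvi_dhi": -2.0}, noise_sd=4.0, seed=seed)
            fit = fit_glm(data, "y", ["ndvi_dhi", "winter_tmin", "latitude"])
            lo, hi = fit.conf_int().loc["ndvi_dhi"]
            hits += lo <= -2.0 <= hi
        assert 0.90 <= hits / 500 <= 0.99


class TestDiagnostics:
    def test_gaussian_residuals_have_straight_qq(self):
        rng = np.random.default_rng(12)
        df = _numeric_frame(rng, n=100, k=1)
        df["y"] = 1 + df["x0"] + rng.normal(0, 1, 100)
        d = residual_diagnostics(fit_glm(df, "y", ["x0"]))
        assert d["qq_correlation"] > 0.98
        assert not d["heteroscedastic"]

    def test_variance_growing_with_mean_is_flagged(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(1, 10, 200)
        y = 5 * x + rng.normal(0, 1, 200) * x ** 2 * 0.2
        df = pd.DataFrame({"x0": x, "y": y})
        d = residual_diagnostics(fit_glm(df, "y", ["x0"]))
        assert d["heteroscedastic"]

    def test_tiny_sample_flagged_low_n(self):
        df = pd.DataFrame({"x0": [1.0, 2.0, 3.0, 4.0], "y": [1.1, 1.9, 3.2, 3.9]})
        d = residual_diagnostics(fit_glm(df, "y", []))
        assert d["low_n"]

    def test_plot_file_written(self, tmp_path):
        rng = np.random.default_rng(14)
        df = _numeric_frame(rng, n=30, k=1)
        df["y"] = df["x0"] + rng.normal(0, 1, 30)
        out = tmp_path / "diag.png"
        residual_diagnostics(fit_glm(df, "y", ["x0"]), plot_path=out)
        assert out.stat().st_size > 0


class TestPeriodAmplitude:
    @staticmethod
    def _metrics(rng, n, slope):
        amp = rng.uniform(0.4, 1.5, n)
        per = 30 + slope * amp + rng.normal(0, 3, n)
        return pd.DataFrame({"is_cyclic": True, "period": per, "amplitude": amp})

    def test_positive_coupling_recovered(self):
        rng = np.random.default_rng(15)
        slope, se = period_amplitude_association(self._metrics(rng, 40, slope=8.0))
        assert slope > 0
        assert abs(slope - 8.0) < 4 * se

    def test_null_coupling_interval_covers_zero(self):
        rng = np.random.default_rng(16)
        cover = 0
        for _ in range(200):
            slope, se = period_amplitude_association(self._metrics(rng, 30, slope=0.0))
            cover += (slope - 1.96 * se) <= 0 <= (slope + 1.96 * se)
        assert cover / 200 >= 0.85

    def test_two_points_rejected(self):
        df = pd.DataFrame({"is_cyclic": [True, True], "period": [30.0, 40.0],
                           "amplitude": [0.5, 1.0]})
        with pytest.raises(InvalidParameterError):
            period_amplitude_association(df)
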