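import dataclasses
import subprocess

import numpy as np
import pandas as pd
import pytest

from hbmon import (
    ModelSpec,
    compare_models,
    fit_additive_model,
    fit_mixed_baseline,
    load_model,
    predict_with_ci,
    save_model,
)
from hbmon.additive_model import FitError


def _rows(x, y, gender="female", patient=None, colname="age"):
    n = len(y)
    return pd.DataFrame(
        {
            "patient_id": patient if patient is not None else [f"p{i}" for i in range(n)],
            "y": y,
            colname: x,
            "gender": gender,
        }
    )


ONE_SMOOTH = ModelSpec(smooth_terms=(("age", 10),), parametric_terms=(), random_intercept=False)


class TestFit:
    def test_constant_response_degenerates_to_intercept(self):
        rows = _rows(np.linspace(0, 1, 50), np.full(50, 8.3))
        m = fit_additive_model(rows, ONE_SMOOTH)
        assert m.beta0 == pytest.approx(8.3, abs=1e-8)
        contrib = m.term_contributions(rows)["s(age)"]
        assert np.abs(contrib).max() < 1e-8
        np.testing.assert_allclose(m.predict(rows), 8.3, atol=1e-8)

    def test_linear_truth_matches_least_squares_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(6, 10, 400)
        noise_sd = 0.3
        y = 7.0 + 0.5 * (x - x.mean()) + rng.normal(0, noise_sd, 400)
        rows = _rows(x, y, colname="past_mean")
        spec = ModelSpec(
            smooth_terms=(("past_mean", 10),), parametric_terms=(), random_intercept=False
        )
        m = fit_additive_model(rows, spec)
        # independent oracle: ordinary least squares on the same rows
        coef = np.polyfit(x, y, 1)
        ols_fit = np.polyval(coef, x)
        assert np.sqrt(np.mean((m.predict(rows) - ols_fit) ** 2)) < 0.1
        # held-out error close to the irreducible noise
        x2 = rng.uniform(6, 10, 400)
        y2 = 7.0 + 0.5 * (x2 - x.mean()) + rng.normal(0, noise_sd, 400)
        mspe = np.mean((m.predict(_rows(x2, y2, colname="past_mean")) - y2) ** 2)
        assert mspe < 1.2 * noise_sd**2

    def test_sinusoidal_curve_recovered(self):
        rng = np.random.default_rng(12)
        n = 2000
        t = rng.uniform(0, 2000, n)
        true = 0.4 * np.sin(2 * np.pi * t / 2000)
        y = 8.0 + true + rng.normal(0, 0.3, n)
        rows = _rows(t, y, colname="time_since_first_days")
        spec = ModelSpec(
            smooth_terms=(("time_since_first_days", 10),),
            parametric_terms=(),
            random_intercept=False,
        )
        m = fit_additive_model(rows, spec)
        grid = np.linspace(0, 2000, 300)
        fitted = m.partial_effect("s(time_since_first_days)", grid)
        truth = 0.4 * np.sin(2 * np.pi * grid / 2000)
        rmse = np.sqrt(np.mean(((fitted - fitted.mean()) - (truth - truth.mean())) ** 2))
        assert rmse < 0.1

    def test_additivity_and_centering(self, small_split):
        m = fit_additive_model(small_split.train)
        contrib = m.term_contributions(small_split.train)
        np.testing.assert_allclose(
            contrib.sum(axis=1), m.predict(small_split.train), atol=1e-10
        )
        for term in ("s(age)", "s(past_mean)", "s(time_since_first_days)"):
            assert abs(contrib[term].mean()) < 1e-8

    def test_penalty_limit_is_the_least_squares_line(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 200)
        y = 8 + 0.3 * np.sin(x) + rng.normal(0, 0.2, 200)
        rows = _rows(x, y)
        m = fit_additive_model(rows, ONE_SMOOTH, fixed_lambda={"s(age)": 1e9})
        line = np.polyval(np.polyfit(x, y, 1), x)
        assert np.abs(m.predict(rows) - line).max() < 1e-5

    def test_edf_within_bounds(self, small_split):
        m = fit_additive_model(small_split.train)
        for _, row in m.smooth_table.iterrows():
            if row["term"].startswith("s("):
                assert 0 < row["edf"] < 10

    def test_constant_covariate_rejected(self):
        rows = _rows(np.full(50, 5.0), np.random.default_rng(0).normal(8, 1, 50))
        with pytest.raises(FitError, match="s\\(age\\)"):
            fit_additive_model(rows, ONE_SMOOTH)

    def test_matches_mgcv_reml_fit(self, tmp_path):
        """Independent oracle: mgcv's penalized-spline REML fit on the same
        data produces near-identical fitted values."""
        rng = np.random.default_rng(3)
        n = 300
        x = np.sort(rng.uniform(0, 10, n))
        y = 2 + np.sin(x) + 0.1 * x**1.5 / 3 + rng.normal(0, 0.3, n)
        data = tmp_path / "d.csv"
        pd.DataFrame({"x": x, "y": y}).to_csv(data, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(
            "library(mgcv)\n"
            f'd <- read.csv("{data}")\n'
            'm <- gam(y ~ s(x, k=10, bs="ps"), data=d, method="REML")\n'
            f'write.csv(data.frame(fit=fitted(m)), "{tmp_path}/fit.csv", row.names=FALSE)\n'
        )
        subprocess.run(["Rscript", str(rscript)], check=True, capture_output=True)
        rfit = pd.read_csv(tmp_path / "fit.csv")["fit"].to_numpy()
        m = fit_additive_model(_rows(x, y), ONE_SMOOTH)
        assert np.sqrt(np.mean((m.predict(_rows(x, y)) - rfit) ** 2)) < 0.02


class TestPrediction:
    def test_zero_variance_intervals_collapse(self):
        rows = _rows(np.linspace(0, 1, 50), np.full(50, 8.3))
        m = fit_additive_model(rows, ONE_SMOOTH)
        preds = predict_with_ci(m, rows, 0.95)
        np.testing.assert_allclose(preds["y_hat"], 8.3, atol=1e-8)
        np.testing.assert_allclose(preds["ci_high"] - preds["ci_low"], 0.0, atol=1e-6)

    def test_wider_level_contains_narrower(self, small_split):
        m = fit_additive_model(small_split.train)
        p95 = predict_with_ci(m, small_split.test, 0.95)
        p99 = predict_with_ci(m, small_split.test, 0.99)
        assert (p99["ci_low"] <= p95["ci_low"]).all()
        assert (p99["ci_high"] >= p95["ci_high"]).all()

    def test_mean_interval_nested_in_prediction_interval(self, small_split):
        m = fit_additive_model(small_split.train)
        pm = predict_with_ci(m, small_split.test, 0.95, interval="mean")
        pp = predict_with_ci(m, small_split.test, 0.95, interval="prediction")
        assert (pp["ci_high"] - pp["ci_low"] >= pm["ci_high"] - pm["ci_low"] - 1e-12).all()

    def test_unseen_gender_errors_and_unseen_patient_warns(self, small_split):
        m = fit_additive_model(small_split.train)
        bad = small_split.test.copy()
        bad.loc[bad.index[0], "gender"] = "other"
        with pytest.raises(FitError, match="gender"):
            m.predict(bad)
        new = small_split.test.copy()
        new["patient_id"] = "never-seen"
        with pytest.warns(UserWarning, match="unseen"):
            preds = m.predict(new)
        offsets = m.random_intercepts
        base = m.predict(small_split.test) - offsets.loc[
            small_split.test["patient_id"]
        ].to_numpy()
        np.testing.assert_allclose(preds, base, atol=1e-10)

    def test_save_load_round_trip(self, small_split, tmp_path):
        m = fit_additive_model(small_split.train)
        save_model(m, tmp_path / "model.npz")
        back = load_model(tmp_path / "model.npz")
        p1 = predict_with_ci(m, small_split.test, 0.95)
        p2 = predict_with_ci(back, small_split.test, 0.95)
        pd.testing.assert_frame_equal(p1, p2)


class TestMixedBaseline:
    def test_linear_world_baseline_close_to_additive(self):
        rng = np.random.default_rng(21)
        n_pat, per = 80, 8
        pid = np.repeat([f"p{i}" for i in range(n_pat)], per)
        offsets = np.repeat(rng.normal(0, 0.5, n_pat), per)
        t = rng.uniform(0, 1000, n_pat * per)
        pm = rng.uniform(7, 9, n_pat * per)
        age = rng.uniform(30, 80, n_pat * per)
        y = 8 + 0.3 * (pm - 8) + 0.0002 * t + offsets + rng.normal(0, 0.3, n_pat * per)
        gender = np.where(np.arange(n_pat * per) % 2 == 0, "female", "male")
        rows = pd.DataFrame(
            {"patient_id": pid, "y": y, "age": age, "past_mean": pm,
             "time_since_first_days": t, "gender": gender}
        )
        train, test = rows.iloc[: n_pat * (per - 1)], rows.iloc[n_pat * (per - 1):]
        gam = fit_additive_model(train)
        lin = fit_mixed_baseline(train)
        mspe_gam = np.mean((gam.predict(test) - test["y"]) ** 2)
        mspe_lin = np.mean((lin.predict(test) - test["y"]) ** 2)
        assert abs(mspe_gam - mspe_lin) < 0.1 * max(mspe_gam, mspe_lin)

    def test_constant_response_intercept_only(self):
        rng = np.random.default_rng(0)
        rows = pd.DataFrame(
            {"patient_id": [f"p{i}" for i in range(40)], "y": 8.3,
             "age": rng.uniform(20, 80, 40), "past_mean": rng.uniform(7, 9, 40),
             "time_since_first_days": rng.uniform(0, 100, 40),
             "gender": ["female", "male"] * 20}
        )
        m = fit_mixed_baseline(rows)
        assert np.mean((m.predict(rows) - 8.3) ** 2) < 1e-10

    def test_strong_nonlinearity_favors_additive_model(self):
        rng = np.random.default_rng(31)
        n = 1500
        t = rng.uniform(0, 2000, n)
        y = 8 + 0.8 * np.sin(2 * np.pi * t / 1000) + rng.normal(0, 0.3, n)
        rows = pd.DataFrame(
            {"patient_id": [f"p{i % 100}" for i in range(n)], "y": y,
             "age": rng.uniform(30, 80, n), "past_mean": rng.uniform(7, 9, n),
             "time_since_first_days": t,
             "gender": np.where(np.arange(n) % 2 == 0, "female", "male")}
        )
        train, test = rows.iloc[:1200], rows.iloc[1200:]
        gam = fit_additive_model(train)
        lin = fit_mixed_baseline(train)
        mspe_gam = np.mean((gam.predict(test) - test["y"]) ** 2)
        mspe_lin = np.mean((lin.predict(test) - test["y"]) ** 2)
        assert mspe_gam < mspe_lin

    def test_matches_statsmodels_mixedlm_slopes(self):
        """Independent oracle for the random-intercept baseline: statsmodels
        MixedLM gives near-identical fixed-effect slopes."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(41)
        n_pat, per = 60, 6
        pid = np.repeat([f"p{i}" for i in range(n_pat)], per)
        offsets = np.repeat(rng.normal(0, 0.6, n_pat), per)
        pm = rng.uniform(7, 9, n_pat * per)
        t = rng.uniform(0, 1000, n_pat * per)
        age = rng.uniform(30, 80, n_pat * per)
        y = 8 + 0.4 * (pm - 8) + offsets + rng.normal(0, 0.25, n_pat * per)
        gender = np.where(np.arange(n_pat * per) % 2 == 0, "female", "male")
        rows = pd.DataFrame(
            {"patient_id": pid, "y": y, "age": age, "past_mean": pm,
             "time_since_first_days": t, "gender": gender}
        )
        mine = fit_mixed_baseline(
            rows, ModelSpec(smooth_terms=(("past_mean", 10),), random_intercept=True)
        )
        my_slope = mine.parametric_table.set_index("term").loc["linear(past_mean)", "estimate"]
        sm_fit = smf.mixedlm("y ~ past_mean", rows, groups=rows["patient_id"]).fit()
        assert my_slope == pytest.approx(sm_fit.params["past_mean"], abs=0.02)


class TestComparison:
    def test_identical_specs_give_zero_delta(self, small_split):
        a = fit_additive_model(small_split.train)
        b = fit_additive_model(small_split.train)
        rep = compare_models(a, b, small_split.train)
        assert rep.delta_aic == pytest.approx(0, abs=1e-6)
        assert rep.f_statistic == 0.0 and rep.p_value == 1.0

    def test_non_nested_specs_rejected(self, small_split):
        full = fit_additive_model(
            small_split.train, ModelSpec(smooth_terms=(("age", 6),), random_intercept=True)
        )
        other = fit_additive_model(
            small_split.train,
            ModelSpec(smooth_terms=(("past_mean", 6),), random_intercept=False),
        )
        with pytest.raises(ValueError, match="nested"):
            compare_models(full, other, small_split.train)

    def test_strong_heterogeneity_detected(self):
        rng = np.random.default_rng(51)
        n_pat, per = 150, 5
        pid = np.repeat([f"p{i}" for i in range(n_pat)], per)
        offsets = np.repeat(rng.normal(0, 1.0, n_pat), per)
        age = rng.uniform(30, 80, n_pat * per)
        y = 8 + offsets + rng.normal(0, 0.3, n_pat * per)
        rows = pd.DataFrame(
            {"patient_id": pid, "y": y, "age": age,
             "time_since_first_days": rng.uniform(0, 1000, n_pat * per),
             "gender": np.where(np.arange(n_pat * per) % 2 == 0, "female", "male")}
        )
        spec = ModelSpec(smooth_terms=(("age", 6),), random_intercept=True)
        full = fit_additive_model(rows, spec)
        red = fit_additive_model(rows, dataclasses.replace(spec, random_intercept=False))
        rep = compare_models(full, red, rows)
        assert rep.p_value < 0.01
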