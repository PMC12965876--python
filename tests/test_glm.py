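"""GLM engine tests: Gaussian log-link fitting, scope-constrained stepwise
selection, VIF, residual diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from conftest import glm_frame
from oracles import ols_stepwise
from soildriver.glm import (
    fit_glm,
    residual_diagnostics,
    stepwise_aic,
    two_stage_selection,
    vif_check,
)


class TestFitGLM:
    def test_intercept_only_matches_numeric_ml_oracle(self, rng):
        df = glm_frame(rng, n=150, k=1, beta=[0.0])
        fit = fit_glm(df, "y", [])
        y = df["y"].to_numpy()
        oracle = minimize_scalar(lambda b0: np.sum((y - np.exp(b0)) ** 2),
                                 bounds=(0, 10), method="bounded", options={"xatol": 1e-12})
        assert fit.params["const"] == pytest.approx(oracle.x, abs=1e-6)
        assert np.allclose(fit.fittedvalues, fit.fittedvalues.iloc[0])

    def test_noiseless_exact_recovery(self, rng):
        x = rng.standard_normal(100)
        df = pd.DataFrame({"x1": x, "y": np.exp(1.0 + 2.0 * x)})
        fit = fit_glm(df, "y", ["x1"])
        assert fit.params["const"] == pytest.approx(1.0, abs=1e-6)
        assert fit.params["x1"] == pytest.approx(2.0, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_monte_carlo_consistency(self, rng):
        x = rng.standard_normal(2000)
        y = np.exp(0.5 + 0.3 * x) + rng.normal(0, 0.1, 2000)
        fit = fit_glm(pd.DataFrame({"x1": x, "y": y}), "y", ["x1"])
        assert fit.params["const"] == pytest.approx(0.5, abs=0.05)
        assert fit.params["x1"] == pytest.approx(0.3, abs=0.05)

    def test_diagnostics_identities(self, rng):
        df = glm_frame(rng, n=200, k=2, beta=[0.05, 0.02])
        fit = fit_glm(df, "y", ["x1", "x2"])
        assert fit.rmse == pytest.approx(np.sqrt(fit.mse), rel=1e-12)
        assert 0.0 <= fit.r2 <= 1.0
        assert np.isfinite(fit.aic)

    def test_categorical_term_reference_coded(self, rng):
        df = glm_frame(rng, n=120, k=1, beta=[0.05])
        df["eco"] = pd.Categorical(rng.choice(["a", "b", "c"], 120))
        fit = fit_glm(df, "y", ["x1", "eco"])
        assert fit.term_columns["eco"] == ["eco_b", "eco_c"]
        assert len(fit.params) == 4  # const + x1 + 2 dummies

    def test_overparameterized_rejected(self, rng):
        df = glm_frame(rng, n=3, k=4)
        with pytest.raises(ValueError, match="must exceed"):
            fit_glm(df, "y", ["x1", "x2", "x3", "x4"])


class TestStepwise:
    def test_empty_move_set_returns_start(self, rng):
        df = glm_frame(rng, n=100, k=2, beta=[0.1, 0.0])
        fit = stepwise_aic(df, "y", ["x1"], ["x1"], ["x1"])
        assert fit.terms == ["x1"]
        assert [m for m, *_ in fit.path] == ["start"]

    def test_aic_strictly_decreases_along_accepted_path(self, rng):
        df = glm_frame(rng, n=200, k=6, beta=[0.08, 0.05, 0, 0, 0, 0])
        fit = stepwise_aic(df, "y", [], [], [f"x{i+1}" for i in range(6)])
        aics = [a for *_, a in fit.path]
        assert all(b < a - 1e-10 for a, b in zip(aics, aics[1:]))
        assert fit.aic <= aics[0]

    def test_scope_lower_never_dropped(self, rng):
        df = glm_frame(rng, n=150, k=4, beta=[0, 0, 0, 0])
        fit = stepwise_aic(df, "y", ["x1", "x2"], ["x1"], ["x1", "x2", "x3", "x4"])
        assert "x1" in fit.terms

    def test_identity_link_reproduces_ols_stepwise_oracle(self, rng):
        # classical least-squares stepwise is the independent reference for
        # the identity-link Gaussian path
        for _ in range(20):
            n, k = 60, 5
            x = rng.standard_normal((n, k))
            beta = rng.choice([0.0, 1.0], size=k)
            y = 2.0 + x @ beta + rng.normal(0, 1.0, n)
            df = pd.DataFrame(x, columns=[f"x{i+1}" for i in range(k)])
            df["y"] = y
            fit = stepwise_aic(df, "y", [], [], list(df.columns[:-1]), link="identity")
            oracle = ols_stepwise(y, {c: df[c].to_numpy() for c in df.columns[:-1]})
            assert sorted(fit.terms) == oracle

    def test_deterministic_selection(self, rng):
        df = glm_frame(rng, n=200, k=5, beta=[0.1, 0.05, 0, 0, 0])
        upper = [f"x{i+1}" for i in range(5)]
        a = stepwise_aic(df, "y", [], [], upper)
        b = stepwise_aic(df, "y", [], [], upper)
        assert a.terms == b.terms and a.aic == b.aic

    def test_invalid_scopes_rejected(self, rng):
        df = glm_frame(rng, n=50, k=2)
        with pytest.raises(ValueError, match="subset"):
            stepwise_aic(df, "y", [], ["x1"], [])
        with pytest.raises(ValueError, match="nested"):
            stepwise_aic(df, "y", ["x2"], [], ["x1"])


class TestTwoStage:
    @pytest.fixture()
    def staged(self, rng):
        n = 300
        soil = rng.standard_normal((n, 3))
        climate = rng.standard_normal((n, 2))
        pest = rng.standard_normal((n, 3))
        eta = 4.5 + 0.08 * soil[:, 0] + 0.06 * climate[:, 0] + 0.1 * pest[:, 0]
        y = np.exp(eta) + rng.normal(0, 5.0, n)
        df = pd.DataFrame(
            np.column_stack([soil, climate, pest]),
            columns=["s1", "s2", "s3", "c1", "c2", "p1", "p2", "p3"],
        )
        df["eco"] = pd.Categorical(rng.choice(["crop", "grass"], n))
        df["y"] = y
        return df

    def test_stage1_terms_locked_into_final_model(self, staged):
        final = two_stage_selection(staged, "y", ["s1", "s2", "s3"], ["c1", "c2"],
                                    ["p1", "p2", "p3"], ecosystem_term="eco")
        assert set(final.stage1.terms) <= set(final.terms)

    def test_stage1_never_contains_pesticides(self, staged):
        final = two_stage_selection(staged, "y", ["s1", "s2", "s3"], ["c1", "c2"],
                                    ["p1", "p2", "p3"], ecosystem_term="eco")
        assert not {"p1", "p2", "p3"} & set(final.stage1.terms)

    def test_group_labels_attached(self, staged):
        final = two_stage_selection(staged, "y", ["s1", "s2", "s3"], ["c1", "c2"],
                                    ["p1", "p2", "p3"], ecosystem_term="eco")
        labels = {final.groups[t] for t in final.terms}
        assert labels <= {"soil", "climate", "pesticides", "ecosystem"}
        assert final.groups.get("p1", "pesticides") == "pesticides"


class TestVIF:
    def test_orthogonal_design_unit_vif(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        df = pd.DataFrame({"x1": x1, "x2": x2, "y": np.exp(4 + 0.01 * x1)})
        fit = fit_glm(df, "y", ["x1", "x2"])
        vifs = vif_check(fit, df)
        assert np.allclose(vifs["gvif"], 1.0, atol=1e-10)

    def test_known_pairwise_correlation_closed_form(self, rng):
        n = 400
        x1 = rng.standard_normal(n)
        x2 = 0.9 * x1 + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        df = pd.DataFrame({"x1": x1, "x2": x2})
        df["y"] = np.exp(4 + 0.01 * x1) + rng.normal(0, 1, n)
        fit = fit_glm(df, "y", ["x1", "x2"])
        vifs = vif_check(fit, df)
        r2 = np.corrcoef(x1, x2)[0, 1] ** 2
        assert np.allclose(vifs["gvif"], 1 / (1 - r2), rtol=1e-10)

    def test_duplicated_column_flagged_infinite(self, rng):
        x = rng.standard_normal(50)
        df = pd.DataFrame({"x1": x, "x2": x})
        df["y"] = np.exp(4 + 0.01 * x) + rng.normal(0, 1, 50)
        fit = fit_glm(df, "y", ["x1", "x2"])
        vifs = vif_check(fit, df)
        assert np.isinf(vifs["gvif"]).all() and vifs["flagged"].all()


class TestResidualDiagnostics:
    def test_normal_vs_heavy_tailed_qq(self, rng):
        n = 500
        x = rng.standard_normal(n)
        mu = np.exp(4 + 0.05 * x)
        normal_noise = rng.normal(0, 5, n)
        t2_noise = 5 * rng.standard_t(2, n)
        df_n = pd.DataFrame({"x1": x, "y": mu + normal_noise})
        df_t = pd.DataFrame({"x1": x, "y": mu + t2_noise})
        qq_n = residual_diagnostics(fit_glm(df_n, "y", ["x1"]))["qq_corr"]
        qq_t = residual_diagnostics(fit_glm(df_t, "y", ["x1"]))["qq_corr"]
        assert qq_n > 0.99
        assert qq_t < qq_n

    def test_zero_residuals_reported_as_perfect_fit(self, rng):
        x = rng.standard_normal(60)
        df = pd.DataFrame({"x1": x, "y": np.exp(1 + 0.5 * x)})
        diag = residual_diagnostics(fit_glm(df, "y", ["x1"]))
        assert diag["perfect_fit"] and diag["qq_corr"] == 1.0
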