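import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import guilddiet as gd
from guilddiet.models import (
    collinearity_screen,
    fit_gls_exponential,
    fit_ols,
    fit_species_models,
    morans_I,
    standardize_predictors,
    transform_response,
)


class TestStandardize:
    def test_z_scores(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out, record = standardize_predictors(df, ["x"])
        np.testing.assert_allclose(out["x"], [-1, 0, 1])
        assert record["x"] == (2.0, 1.0)

    def test_idempotent_on_standardized(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50)
        x = (x - x.mean()) / x.std(ddof=1)
        out, _ = standardize_predictors(pd.DataFrame({"x": x}), ["x"])
        np.testing.assert_allclose(out["x"], x, atol=1e-12)

    def test_constant_column_dropped(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        out, record = standardize_predictors(df, ["x", "y"])
        assert "x" not in out.columns and "y" in record


class TestTransforms:
    def test_log10(self):
        assert transform_response([100.0], "log10")[0] == pytest.approx(2.0)

    def test_logit_symmetry_point(self):
        assert transform_response([0.5], "logit")[0] == 0.0

    def test_logit_clamps_boundaries(self):
        hi = transform_response([1.0], "logit")[0]
        assert hi == pytest.approx(np.log(0.999 / 0.001), abs=1e-12)
        assert hi == pytest.approx(6.9068, abs=1e-4)
        lo = transform_response([0.0], "logit")[0]
        assert lo == pytest.approx(-hi, abs=1e-12)

    def test_log10_rejects_nonpositive(self):
        with pytest.raises(gd.GuildDietError):
            transform_response([0.0], "log10")


class TestCollinearity:
    def test_correlated_pair_drops_precipitation(self):
        rng = np.random.default_rng(1)
        temp = rng.normal(15, 3, 40)
        precip = -30.0 * temp + rng.normal(0, 35, 40)  # strongly negative r
        df = pd.DataFrame({"temperature": temp, "precipitation": precip,
                           "tree_cover": rng.uniform(0, 80, 40)})
        r = np.corrcoef(temp, precip)[0, 1]
        assert r < -0.65
        retained, report = collinearity_screen(df, ["temperature", "precipitation", "tree_cover"])
        assert "precipitation" not in retained and "temperature" in retained
        assert len(report) == 3  # all pairwise r reported

    def test_orthogonal_all_retained(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"temperature": rng.normal(0, 1, 60),
                           "precipitation": rng.normal(0, 1, 60)})
        retained, _ = collinearity_screen(df, ["temperature", "precipitation"])
        assert retained == ["temperature", "precipitation"]

    def test_perfect_correlation_r_one(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]})
        _, report = collinearity_screen(df, ["a", "b"], r_threshold=1.1)
        assert report["pearson_r"].iloc[0] == pytest.approx(1.0)


class TestOLS:
    def test_exact_fit(self):
        x = np.arange(10, dtype=float)
        fit = fit_ols(2.0 * x, pd.DataFrame({"x": x}))
        assert fit.coef("x") == pytest.approx(2.0, abs=1e-12)
        np.testing.assert_allclose(fit.residuals, 0, atol=1e-10)

    def test_intercept_only_is_mean(self):
        y = np.array([1.0, 2.0, 6.0])
        fit = fit_ols(y, pd.DataFrame(index=range(3)))
        assert fit.beta[0] == pytest.approx(y.mean())

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n, p = 40, 3
            X = pd.DataFrame(rng.normal(0, 1, (n, p)), columns=list("abc"))
            y = rng.normal(0, 1, n)
            fit = fit_ols(y, X)
            Xm = np.column_stack([np.ones(n), X.to_numpy()])
            beta = np.linalg.inv(Xm.T @ Xm) @ Xm.T @ y
            np.testing.assert_allclose(fit.beta, beta, rtol=1e-10)

    def test_residuals_sum_to_zero_with_intercept(self):
        rng = np.random.default_rng(4)
        fit = fit_ols(rng.normal(0, 1, 30), pd.DataFrame({"x": rng.normal(0, 1, 30)}))
        assert abs(fit.residuals.sum()) < 1e-10
        assert fit.df == 28

    def test_rank_deficiency_names_columns(self):
        x = np.arange(10, dtype=float)
        X = pd.DataFrame({"x1": x, "x2": 2 * x})
        with pytest.raises(gd.GuildDietError, match="x2"):
            fit_ols(np.ones(10), X)


class TestMoran:
    def test_expected_value_analytic(self):
        rng = np.random.default_rng(5)
        m = morans_I(rng.normal(0, 1, 11), rng.uniform(38, 42, 11), rng.uniform(5, 11, 11))
        assert m.expected == pytest.approx(-0.1, abs=1e-15)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(6)
        e = rng.normal(0, 1, 20)
        lat, lon = rng.uniform(38, 42, 20), rng.uniform(5, 11, 20)
        m1 = morans_I(e, lat, lon)
        m2 = morans_I(e[::-1], lat[::-1], lon[::-1])
        assert m1.I == pytest.approx(m2.I, abs=1e-12)

    def test_coincident_points_error(self):
        lat = np.array([40.0, 40.0, 41.0, 42.0, 43.0])
        lon = np.array([10.0, 10.0, 10.0, 10.0, 10.0])
        with pytest.raises(gd.GuildDietError, match="pool"):
            morans_I(np.arange(5.0), lat, lon)

    def test_gradient_detected_vs_permutation_oracle(self):
        rng = np.random.default_rng(7)
        n = 40
        lat = rng.uniform(38, 42, n)
        lon = rng.uniform(5, 11, n)
        e = (lat - lat.mean()) + rng.normal(0, 0.2, n)  # smooth north-south trend
        m = morans_I(e, lat, lon)
        assert m.I > m.expected and m.p < 0.01
        # permutation oracle
        obs = m.I
        perm = np.array(
            [morans_I(rng.permutation(e), lat, lon).I for _ in range(499)]
        )
        p_perm = (1 + np.sum(perm >= obs)) / 500
        assert p_perm < 0.01

    def test_matches_R_ape_reference(self, tmp_path):
        """ape::Moran.I row-normalizes weights and uses the randomization
        variance; with those settings the results must agree exactly."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(8)
        n = 15
        lat, lon = rng.uniform(38, 42, n), rng.uniform(5, 11, n)
        e = rng.normal(0, 1, n)
        d = gd.haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
        np.savetxt(tmp_path / "d.csv", d, delimiter=",")
        np.savetxt(tmp_path / "e.csv", e)
        script = (
            'suppressMessages(library(ape));'
            f'd <- as.matrix(read.csv("{tmp_path}/d.csv", header=FALSE));'
            f'e <- scan("{tmp_path}/e.csv", quiet=TRUE);'
            "w <- 1/d; diag(w) <- 0; res <- Moran.I(e, w);"
            'cat(sprintf("%.15g", c(res$observed, res$expected, res$sd, res$p.value)), sep=",")'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        obs, exp, sd, p = map(float, out.stdout.strip().split(","))
        m = morans_I(e, lat, lon, variance="randomization", row_normalize=True)
        assert m.I == pytest.approx(obs, abs=1e-9)
        assert m.expected == pytest.approx(exp, abs=1e-12)
        assert np.sqrt(m.var) == pytest.approx(sd, abs=1e-9)
        assert m.p == pytest.approx(p, abs=1e-9)


class TestGLS:
    def test_identity_correlation_reproduces_ols(self):
        # independent errors: GLS beta within 2 SE of OLS beta
        rng = np.random.default_rng(9)
        n = 60
        lat, lon = rng.uniform(35, 45, n), rng.uniform(-8, 36, n)
        X = pd.DataFrame({"x": rng.normal(0, 1, n)})
        y = 1.0 + 0.5 * X["x"].to_numpy() + rng.normal(0, 0.3, n)
        ols = fit_ols(y, X)
        gls = fit_gls_exponential(y, X, lat, lon)
        assert abs(gls.coef("x") - ols.coef("x")) < 2 * ols.se[1]

    def test_intercept_only_identity_C_is_mean(self):
        from guilddiet.models import _gls_profile

        rng = np.random.default_rng(10)
        n = 30
        lat = np.linspace(35, 45, n)
        lon = np.linspace(-8, 36, n)
        y = rng.normal(5, 1, n)
        d = gd.haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
        # rho far below the smallest distance: C is the identity exactly
        beta = _gls_profile(y, np.ones((n, 1)), d, rho=1e-3)[0]
        assert beta[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_recovers_planted_range(self):
        rng = np.random.default_rng(11)
        ok = 0
        for _ in range(25):
            n = 80
            lat, lon = rng.uniform(38, 42, n), rng.uniform(5, 11, n)
            d = gd.haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
            L = np.linalg.cholesky(np.exp(-d / 100.0) + 1e-10 * np.eye(n))
            y = 1.0 + L @ rng.standard_normal(n)
            fit = fit_gls_exponential(y, pd.DataFrame(index=range(n)), lat, lon)
            if fit.method == "GLS_exp" and 50.0 <= fit.rho_km <= 200.0:
                ok += 1
        assert ok >= 20  # within factor 2 in >= 80% of replicates


class TestSpeciesModels:
    def test_island_term_auto_dropped(self, sim_metrics):
        _, _, mt = sim_metrics
        mono = mt.copy()
        mono.loc[mono["predator"] == "EEO", "island"] = False
        fits, _ = fit_species_models(mono, "EEO", "geographic")
        for f in fits:
            assert "island" not in f.terms

    def test_four_responses_per_set(self, sim_metrics):
        _, _, mt = sim_metrics
        fits_g, morans_g = fit_species_models(mt, "LEO", "geographic")
        fits_e, _ = fit_species_models(mt, "LEO", "environmental")
        assert len(fits_g) == 4 and len(fits_e) == 4
        assert len(morans_g) == 4
        assert {f.response for f in fits_g} == {"H", "J", "mean_prey_size_g", "prop_mammals"}

    def test_transforms_recorded(self, sim_metrics):
        _, _, mt = sim_metrics
        fits, _ = fit_species_models(mt, "TAW", "environmental")
        kinds = {f.response: f.transform for f in fits}
        assert kinds["mean_prey_size_g"] == "log10"
        assert kinds["prop_mammals"] == "logit"
        assert kinds["H"] == "identity"
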