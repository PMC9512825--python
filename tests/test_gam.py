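import numpy as np
import pandas as pd
import pytest

from breakclust.gam import (GAMSpec, build_design, explained_deviance,
                            fit_background, fit_gam, partial_effects,
                            term_significance)


def gamma_noise(rng, mu, shape):
    return rng.gamma(shape, mu / shape)


class TestDesign:
    def test_factor_only_design_is_intercept_plus_dummy(self, rng):
        cov = pd.DataFrame({"FS": rng.integers(0, 2, 100).astype(float)})
        d = build_design(cov, GAMSpec(linear_factors=["FS"]))
        assert d.p == 2

    def test_smooth_has_k_minus_one_columns_per_by_level(self, rng):
        n = 300
        cov = pd.DataFrame({"x": rng.random(n),
                            "LAD": rng.integers(0, 2, n).astype(float)})
        d = build_design(cov, GAMSpec(smooths=[("x", "LAD")], basis_dim=10))
        smooth_terms = [t for t in d.terms if t.kind == "smooth"]
        assert len(smooth_terms) == 2                      # one per LAD level
        assert all(t.ncol == 9 for t in smooth_terms)      # k - 1 constrained

    def test_tensor_of_two_k5_marginals_is_at_most_16_columns(self, rng):
        n = 400
        cov = pd.DataFrame({"a": rng.random(n), "b": rng.random(n)})
        d = build_design(cov, GAMSpec(tensors=[(("a", "b"), None)],
                                      tensor_basis_dim=5))
        t = [t for t in d.terms if t.kind == "tensor"][0]
        assert t.ncol <= 16
        assert np.linalg.matrix_rank(d.X) == d.p           # full rank

    def test_small_basis_dim_rejected(self):
        with pytest.raises(ValueError):
            GAMSpec(basis_dim=3)


class TestFit:
    def test_intercept_only_fits_the_mean(self, rng):
        y = gamma_noise(rng, np.full(200, 3.0), 20)
        d = build_design(pd.DataFrame(index=range(200)), GAMSpec())
        fit = fit_gam(d, y)
        assert np.allclose(fit.fitted, y.mean(), rtol=1e-6)
        assert explained_deviance(fit) == pytest.approx(0.0, abs=1e-12)

    def test_linear_coefficient_recovery_within_two_se(self):
        rng = np.random.default_rng(5)
        n = 5000
        x = rng.random(n)
        mu = 2.0 + 3.0 * x
        y = gamma_noise(rng, mu, 50)
        d = build_design(pd.DataFrame({"x": x}), GAMSpec(linear_terms=["x"]))
        fit = fit_gam(d, y)
        col = [t for t in d.terms if t.name == "x"][0].cols.start
        slope = fit.beta[col]
        se = np.sqrt(fit.cov_beta[col, col])
        assert abs(slope - 3.0) < 2 * se

    def test_smooth_function_recovery(self):
        rng = np.random.default_rng(6)
        n = 5000
        x = np.sort(rng.random(n))
        truth = 3.0 + np.sin(2 * np.pi * x)
        y = gamma_noise(rng, truth, 60)
        d = build_design(pd.DataFrame({"x": x}), GAMSpec(smooths=[("x", None)]))
        fit = fit_gam(d, y)
        rmse = np.sqrt(np.mean((fit.fitted - truth) ** 2))
        assert rmse < 0.05

    def test_negative_working_response_rejected(self, rng):
        d = build_design(pd.DataFrame(index=range(10)), GAMSpec())
        with pytest.raises(ValueError):
            fit_gam(d, np.r_[np.ones(9), -1.0])

    def test_fit_invariant_under_row_reordering(self):
        rng = np.random.default_rng(7)
        n = 500
        cov = pd.DataFrame({"x": rng.random(n),
                            "FS": rng.integers(0, 2, n).astype(float)})
        y = gamma_noise(rng, 2 + cov["x"], 30)
        spec = GAMSpec(linear_factors=["FS"], smooths=[("x", None)])
        f1 = fit_gam(build_design(cov, spec), y, lambdas={"smooth": 1.0})
        perm = rng.permutation(n)
        f2 = fit_gam(build_design(cov.iloc[perm].reset_index(drop=True), spec),
                     y[perm], lambdas={"smooth": 1.0})
        assert np.allclose(f1.fitted[perm], f2.fitted, atol=1e-6)

    def test_sign_reversal_round_trip(self):
        rng = np.random.default_rng(8)
        bpp = -rng.uniform(3, 5, size=300)
        fit = fit_background(pd.DataFrame(index=range(300)), bpp, spec=GAMSpec())
        assert fit.fitted_bpp == pytest.approx(bpp.mean(), abs=1e-6)


class TestExplainedDeviance:
    def test_nested_models_never_lose_deviance(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = 300
            cov = pd.DataFrame({"x": rng.random(n)})
            y = gamma_noise(rng, 2 + cov["x"], 40)
            d0 = build_design(cov, GAMSpec())
            d1 = build_design(cov, GAMSpec(linear_terms=["x"]))
            ed0 = explained_deviance(fit_gam(d0, y))
            ed1 = explained_deviance(fit_gam(d1, y))
            assert ed1 >= ed0 - 1e-10

    def test_true_covariates_beat_permuted(self):
        rng = np.random.default_rng(10)
        n = 5000
        cov = pd.DataFrame({"x": rng.random(n),
                            "z": rng.random(n)})
        mu = 2.0 + 1.5 * cov["x"] + np.sin(2 * np.pi * cov["z"]) * 0.5 + 0.6
        y = gamma_noise(rng, mu.to_numpy(), 40)
        spec = GAMSpec(smooths=[("x", None), ("z", None)])
        ed_true = explained_deviance(fit_gam(build_design(cov, spec), y))
        perm = cov.sample(frac=1, random_state=0).reset_index(drop=True)
        ed_perm = explained_deviance(fit_gam(build_design(perm, spec), y))
        assert ed_true - ed_perm >= 0.1


class TestTermSignificance:
    def test_null_term_type_one_error_is_calibrated(self):
        rng = np.random.default_rng(11)
        n, reps = 400, 200
        rejections = 0
        for _ in range(reps):
            cov = pd.DataFrame({"null": rng.integers(0, 2, n).astype(float)})
            y = gamma_noise(rng, np.full(n, 3.0), 30)
            fit = fit_gam(build_design(cov, GAMSpec(linear_factors=["null"])), y)
            p = term_significance(fit)["p_value"].iloc[0]
            rejections += p < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_strong_effect_is_detected(self):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(20):
            n = 500
            cov = pd.DataFrame({"f": rng.integers(0, 2, n).astype(float)})
            y = gamma_noise(rng, 3.0 + 1.0 * cov["f"].to_numpy(), 30)
            fit = fit_gam(build_design(cov, GAMSpec(linear_factors=["f"])), y)
            hits += term_significance(fit)["p_value"].iloc[0] < 1e-4
        assert hits >= 19

    def test_single_level_factor_dropped_with_no_p_value(self, rng):
        cov = pd.DataFrame({"f": np.zeros(50)})
        fit = fit_gam(build_design(cov, GAMSpec(linear_factors=["f"])),
                      gamma_noise(rng, np.full(50, 2.0), 20))
        assert "f" not in term_significance(fit)["term"].tolist()


class TestPartialEffects:
    def test_additivity_of_term_contributions(self):
        rng = np.random.default_rng(13)
        n = 400
        cov = pd.DataFrame({"x": rng.random(n),
                            "FS": rng.integers(0, 2, n).astype(float)})
        y = gamma_noise(rng, 2 + cov["x"] + 0.5 * cov["FS"], 40)
        spec = GAMSpec(linear_factors=["FS"], smooths=[("x", None)])
        d = build_design(cov, spec)
        fit = fit_gam(d, y, lambdas={"smooth": 1.0})
        total = np.zeros(n)
        for t in d.terms:
            total += t.builder(cov) @ fit.beta[t.cols]
        assert np.allclose(total, fit.fitted, atol=1e-6)

    def test_linear_truth_lies_inside_band(self):
        rng = np.random.default_rng(14)
        n = 2000
        x = rng.random(n)
        y = gamma_noise(rng, 3.0 + 1.0 * x, 50)
        d = build_design(pd.DataFrame({"x": x}), GAMSpec(smooths=[("x", None)]))
        fit = fit_gam(d, y)
        grid = np.linspace(0.05, 0.95, 30)
        pe = partial_effects(fit, "s(x)", grid)
        centred_truth = grid - x.mean()     # slope-1 effect, centred
        inside = ((pe["lower"] <= centred_truth + 0.1)
                  & (centred_truth - 0.1 <= pe["upper"]))
        assert inside.mean() > 0.9

    def test_tensor_surface_shape(self):
        rng = np.random.default_rng(15)
        n = 600
        cov = pd.DataFrame({"a": rng.random(n), "b": rng.random(n)})
        y = gamma_noise(rng, 3 + cov["a"] * cov["b"], 40)
        d = build_design(cov, GAMSpec(tensors=[(("a", "b"), None)]))
        fit = fit_gam(d, y, lambdas={"tensor": 1.0})
        g = np.linspace(0.1, 0.9, 7)
        surf = partial_effects(fit, "te(a,b)", (g, g))
        assert len(surf) == 49
        assert {"effect", "se", "lower", "upper"} <= set(surf.columns)


def test_cross_check_against_mgcv_on_single_smooth(tmp_path):
    """Independent oracle: mgcv's Gamma-identity GAM on the same data."""
    import subprocess
    rng = np.random.default_rng(21)
    n = 800
    x = np.sort(rng.random(n))
    truth = 3.0 + np.sin(2 * np.pi * x)
    y = rng.gamma(60, truth / 60)
    df = pd.DataFrame({"x": x, "y": y})
    csv = tmp_path / "d.csv"
    out = tmp_path / "fit.csv"
    df.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        f'd <- read.csv("{csv}")\n'
        'library(mgcv)\n'
        'm <- gam(y ~ s(x, bs="ps", k=10), family=Gamma(link="identity"), data=d)\n'
        f'write.csv(data.frame(mu=fitted(m)), "{out}", row.names=FALSE)\n')
    subprocess.run(["Rscript", "--vanilla", str(script)], check=True,
                   capture_output=True)
    mu_mgcv = pd.read_csv(out)["mu"].to_numpy()
    fit = fit_gam(build_design(df[["x"]], GAMSpec(smooths=[("x", None)])), y)
    rmse = np.sqrt(np.mean((fit.fitted - mu_mgcv) ** 2))
    assert rmse < 0.05
    assert np.corrcoef(fit.fitted, mu_mgcv)[0, 1] > 0.99
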