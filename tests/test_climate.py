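import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import commstruct as cs
from commstruct.climate import _pairwise_gc_km


def lattice_meta(n_side=10, spacing=0.5, seed=0):
    rng = np.random.default_rng(seed)
    xs, ys = np.meshgrid(np.arange(n_side), np.arange(n_side))
    n = n_side * n_side
    return cs.SiteMetadata(pd.DataFrame({
        "lon": xs.ravel() * spacing, "lat": ys.ravel() * spacing,
        "biome": "B", "Bio1": 1 + rng.random(n), "Bio4": 1 + rng.random(n),
        "Bio12": rng.random(n), "Bio14": rng.random(n),
        "Bio15": rng.random(n)},
        index=[f"s{i}" for i in range(n)]))


class TestScreenCollinear:
    def test_exact_duplicate_dropped(self, rng):
        x1 = rng.standard_normal(50)
        X = pd.DataFrame({"x1": x1, "x2": x1})
        retained, dropped = cs.screen_collinear(X, 0.75)
        assert retained == ["x1"]
        assert dropped[0][:2] == ("x2", "x1")

    def test_uncorrelated_all_retained(self, rng):
        X = pd.DataFrame(rng.standard_normal((200, 3)),
                         columns=["a", "b", "c"])
        retained, dropped = cs.screen_collinear(X, 0.75)
        assert retained == ["a", "b", "c"] and not dropped

    def test_greedy_trace_keeps_only_first(self, rng):
        # r(1,2) and r(1,3) high, r(2,3) low: 2 and 3 both clash with the
        # already-retained 1, so only 1 survives
        z = rng.standard_normal(2000)
        e2 = rng.standard_normal(2000)
        e3 = -e2 + 0.3 * rng.standard_normal(2000)
        X = pd.DataFrame({"x1": z, "x2": z + 0.3 * e2, "x3": z + 0.3 * e3})
        corr = X.corr()
        assert corr.loc["x1", "x2"] > 0.9 and corr.loc["x1", "x3"] > 0.9
        assert abs(corr.loc["x2", "x3"]) < 0.85
        retained, _ = cs.screen_collinear(X, 0.9)
        assert retained == ["x1"]

    def test_constant_covariate_errors(self):
        X = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            cs.screen_collinear(X, 0.75)


class TestTransformClimate:
    def test_transforms(self, toy):
        raw = toy["meta"].data.copy()
        raw.loc["s1", ["Bio4", "Bio14", "Bio15"]] = [1.0, 0.0, 4.0]
        meta = cs.SiteMetadata(raw)
        out = cs.transform_climate(meta, standardise=False)
        assert out.loc["s1", "Bio4"] == pytest.approx(0.0)   # log 1
        assert out.loc["s1", "Bio14"] == pytest.approx(0.0)  # log1p 0
        assert out.loc["s1", "Bio15"] == pytest.approx(2.0)  # sqrt 4

    def test_standardised_columns(self, small_world):
        out = cs.transform_climate(small_world["meta"])
        assert np.allclose(out.mean(), 0, atol=1e-12)
        assert np.allclose(out.std(ddof=1), 1, atol=1e-12)

    def test_domain_violation_names_site(self, toy):
        raw = toy["meta"].data.copy()
        raw.loc["s2", "Bio4"] = -1.0
        with pytest.raises(ValueError, match="s2"):
            cs.transform_climate(cs.SiteMetadata(raw))


class TestAicc:
    def test_formula_arithmetic(self):
        assert cs.aicc(-47.0, 3, 10) == pytest.approx(94 + 6 + 24 / 6)

    def test_large_n_limit_is_aic(self):
        assert cs.aicc(-10.0, 3, 10 ** 9) == pytest.approx(20 + 6, abs=1e-6)

    def test_k_near_n_correction_dominates(self):
        n, k = 10, 8
        val = cs.aicc(0.0, k, n)
        assert val == pytest.approx(2 * k + 2 * k * (k + 1) / 1)

    def test_undefined_when_n_too_small(self):
        with pytest.raises(ValueError):
            cs.aicc(0.0, 9, 10)


class TestAllSubsetsOLS:
    def test_model_count_is_2_to_p(self, rng):
        X = pd.DataFrame(rng.standard_normal((100, 5)),
                         columns=list("abcde"))
        y = rng.standard_normal(100)
        fits, _ = cs.all_subsets_ols(y, X)
        assert len(fits) == 32

    def test_akaike_weights_sum_to_one(self, rng):
        X = pd.DataFrame(rng.standard_normal((80, 3)), columns=list("abc"))
        y = X["a"].to_numpy() + 0.5 * rng.standard_normal(80)
        fits, _ = cs.all_subsets_ols(y, X)
        delta = np.array([f.aicc for f in fits]) - fits[0].aicc
        w = np.exp(-delta / 2)
        w /= w.sum()
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_true_predictor_dominates_importance(self, rng):
        x1 = rng.standard_normal(200)
        x2 = rng.standard_normal(200)
        y = 2 * x1 + 0.1 * rng.standard_normal(200)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        _, imp = cs.all_subsets_ols(y, X)
        assert imp["x1"] > 0.99
        assert imp["x2"] < 0.5

    def test_standardised_coefficients_scale_invariant(self, rng):
        x = rng.standard_normal(150)
        y = 1.5 * x + rng.standard_normal(150)
        Xa = pd.DataFrame({"x": (x - x.mean()) / x.std(ddof=1)})
        xr = 1000 * x + 7  # affine rescaling, then re-standardised
        Xb = pd.DataFrame({"x": (xr - xr.mean()) / xr.std(ddof=1)})
        fa, _ = cs.all_subsets_ols(y, Xa)
        fb, _ = cs.all_subsets_ols(y, Xb)
        assert fa[0].coefficients["x"] == pytest.approx(
            fb[0].coefficients["x"], abs=1e-10)

    def test_rank_deficient_errors(self, rng):
        x = rng.standard_normal(50)
        X = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(ValueError, match="rank"):
            cs.all_subsets_ols(rng.standard_normal(50), X)


class TestGreatCircle:
    def test_identical_points(self):
        assert cs.great_circle_km(10, 10, 10, 10) == 0.0

    def test_antipodal_equator(self):
        assert cs.great_circle_km(0, 0, 180, 0) == pytest.approx(
            np.pi * 6371, rel=1e-6)

    def test_one_degree_longitude_at_equator(self):
        assert cs.great_circle_km(0, 0, 1, 0) == pytest.approx(
            6371 * np.pi / 180, rel=1e-6)

    def test_pairwise_matches_scalar(self, rng):
        coords = np.column_stack([rng.uniform(-20, 50, 6),
                                  rng.uniform(-35, 35, 6)])
        D = _pairwise_gc_km(coords)
        for i in range(6):
            for j in range(6):
                assert D[i, j] == pytest.approx(cs.great_circle_km(
                    *coords[i], *coords[j]), abs=1e-6)


class TestBuildWeights:
    def test_knn2_three_collinear_sites(self):
        meta = cs.SiteMetadata(pd.DataFrame({
            "lon": [0.0, 1.0, 2.0], "lat": 0.0, "biome": "B",
            "Bio1": 1.0, "Bio4": 1.0, "Bio12": 1.0, "Bio14": 1.0,
            "Bio15": 1.0}, index=["a", "b", "c"]))
        W = cs.build_weights(meta, "knn2")
        assert np.allclose(W.W, (1 - np.eye(3)) / 2)

    def test_band_all_isolated_warns(self, caplog):
        meta = cs.SiteMetadata(pd.DataFrame({
            "lon": [0.0, 90.0], "lat": [0.0, 0.0], "biome": "B",
            "Bio1": 1.0, "Bio4": 1.0, "Bio12": 1.0, "Bio14": 1.0,
            "Bio15": 1.0}, index=["a", "b"]))
        with caplog.at_level("WARNING", logger="commstruct"):
            W = cs.build_weights(meta, "band1500")
        assert W.W.sum() == 0
        assert any("isolated" in r.message for r in caplog.records)

    def test_knn_k_too_large_errors(self):
        meta = lattice_meta(2)  # 4 sites
        with pytest.raises(ValueError, match="knn"):
            cs.build_weights(meta, "knn6")

    def test_rows_standardised_and_k_neighbours(self):
        meta = lattice_meta(5)
        W = cs.build_weights(meta, "knn6")
        assert np.allclose(W.W.sum(axis=1), 1.0)
        assert ((W.binary > 0).sum(axis=1) == 6).all()
        assert np.allclose(np.diag(W.W), 0.0)


class TestMoransI:
    def test_expected_value_closed_form(self, rng):
        meta = lattice_meta(4)  # 16 sites
        W = cs.build_weights(meta, "knn2")
        m = cs.morans_i(rng.standard_normal(16), W, n_perm=99, seed=0)
        assert m["expected"] == pytest.approx(-1.0 / 15)

    def test_smooth_gradient_detected(self):
        meta = lattice_meta(7)
        W = cs.build_weights(meta, "knn6")
        grad = meta.data["lon"].to_numpy() + meta.data["lat"].to_numpy()
        m = cs.morans_i(grad, W, n_perm=999, seed=1)
        assert m["I"] > 0
        assert m["p_perm"] <= 0.05

    def test_null_mean_matches_expectation(self, rng):
        meta = lattice_meta(6)
        W = cs.build_weights(meta, "knn6")
        n = 36
        Is = [cs.morans_i(rng.standard_normal(n), W, n_perm=1,
                          seed=i)["I"] for i in range(300)]
        se = np.std(Is, ddof=1) / np.sqrt(300)
        assert abs(np.mean(Is) - (-1 / (n - 1))) < 3 * se

    def test_null_calibration(self, rng):
        meta = lattice_meta(5)
        W = cs.build_weights(meta, "knn2")
        rej = 0
        reps = 200
        for i in range(reps):
            m = cs.morans_i(rng.standard_normal(25), W, n_perm=99, seed=i)
            rej += m["p_perm"] <= 0.05
        # one-sided 5% level; binomial band
        assert abs(rej / reps - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_constant_residuals_error(self):
        meta = lattice_meta(3)
        W = cs.build_weights(meta, "knn2")
        with pytest.raises(ValueError, match="constant"):
            cs.morans_i(np.ones(9), W)


class TestSarErrorFit:
    def test_lambda_fixed_zero_reproduces_ols(self, rng):
        meta = lattice_meta(8)
        W = cs.build_weights(meta, "knn6")
        X = rng.standard_normal((64, 2))
        y = X @ [2.0, -1.0] + rng.standard_normal(64)
        sar = cs.sar_error_fit(y, X, W, standardise_y=False, lam_fixed=0.0)
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        assert np.allclose(list(sar.coefficients.values()), ols.params,
                           atol=1e-8)

    def test_lambda_near_zero_when_independent(self, rng):
        meta = lattice_meta(14)  # n = 196
        W = cs.build_weights(meta, "knn6")
        X = rng.standard_normal((196, 2))
        y = X @ [1.0, 0.5] + rng.standard_normal(196)
        fit = cs.sar_error_fit(y, X, W, standardise_y=False)
        assert abs(fit.lam) < 0.25
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        assert np.allclose(list(fit.coefficients.values()), ols.params,
                           atol=2 * np.max(ols.bse))

    def test_lambda_recovery(self, rng):
        meta = lattice_meta(14)
        n = 196
        W = cs.build_weights(meta, "knn6")
        lams = []
        for _ in range(8):
            X = rng.standard_normal((n, 2))
            u = np.linalg.solve(np.eye(n) - 0.7 * W.W,
                                rng.standard_normal(n))
            y = X @ [1.0, -0.5] + u
            lams.append(cs.sar_error_fit(y, X, W,
                                         standardise_y=False).lam)
        assert 0.6 < np.mean(lams) < 0.8

    def test_pseudo_r2_zero_when_no_signal_gain(self, rng):
        # loglik1 == loglik0 <=> pseudo R2 == 0; intercept-only SAR with
        # lam fixed at 0 is exactly the baseline model
        meta = lattice_meta(6)
        W = cs.build_weights(meta, "knn2")
        y = rng.standard_normal(36)
        fit = cs.sar_error_fit(y, np.empty((36, 0)), W,
                               standardise_y=False, lam_fixed=0.0)
        assert fit.pseudo_r2 == pytest.approx(0.0, abs=1e-10)


class TestSelectAndReport:
    def _responses(self, rng, lam):
        meta = lattice_meta(10, seed=3)
        n = 100
        X = pd.DataFrame(rng.standard_normal((n, 2)), columns=["a", "b"],
                         index=meta.sites)
        W = cs.build_weights(meta, "knn6")
        eps = rng.standard_normal(n)
        u = np.linalg.solve(np.eye(n) - lam * W.W, eps) if lam else eps
        y = X.to_numpy() @ [1.0, -0.5] + u
        return y, X, meta

    def test_independent_data_reports_ols(self, rng):
        y, X, meta = self._responses(rng, lam=0.0)
        rep = cs.select_and_report(y, X, meta, n_perm=199, seed=2,
                                   schemes=("knn6",))
        assert rep["chosen_type"] == "ols"

    def test_autocorrelated_data_reports_sar(self, rng):
        y, X, meta = self._responses(rng, lam=0.8)
        rep = cs.select_and_report(y, X, meta, n_perm=199, seed=2,
                                   schemes=("knn6",))
        assert rep["chosen_type"] == "sar_error"
        assert rep["sar_by_scheme"]["knn6"].lam > 0.4
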