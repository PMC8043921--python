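"""Logistic fitting, screening, L1 selection and the 12-model suite."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import approx_fprime, minimize
from scipy.special import expit, logit

from petradiomics.models import (
    MODEL_NAMES,
    OneClassError,
    build_model_suite,
    encode_clinical,
    fit_logistic,
    lasso_select,
    lrt_pvalue,
    univariable_screen,
)
from petradiomics.synthcohort import (
    CohortSpec,
    fixture_clinical_group1,
    fixture_clinical_group2,
    generate_cohort,
)


class TestFitLogistic:
    def test_intercept_only_closed_form_on_study_counts(self):
        data = encode_clinical(fixture_clinical_group1())
        m = fit_logistic(data, [])
        assert m.params["intercept"] == pytest.approx(float(logit(21 / 96)), abs=1e-6)
        assert m.llf == pytest.approx(m.llnull, abs=1e-8)

    def test_one_class_rejected(self):
        df = pd.DataFrame({"x": np.arange(10.0), "response": np.ones(10, dtype=int)})
        with pytest.raises(OneClassError):
            fit_logistic(df, ["x"])

    def test_rank_deficiency_names_collinear_term(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.standard_normal(50)})
        df["x_copy"] = 2.0 * df["x"]
        df["response"] = rng.integers(0, 2, 50)
        with pytest.raises(ValueError, match="x_copy"):
            fit_logistic(df, ["x", "x_copy"])

    def test_aic_identity_and_nesting(self):
        cohort = generate_cohort(CohortSpec(n_patients=300, n_features=14,
                                            beta={"her2": -1.0}, seed=1))
        small = fit_logistic(cohort.features, ["her2"])
        big = fit_logistic(cohort.features, ["her2", "cT_T3-4a"])
        assert small.aic == pytest.approx(2 * 2 - 2 * small.llf)
        assert big.aic == pytest.approx(2 * 3 - 2 * big.llf)
        assert big.llf >= small.llf - 1e-8  # adding a covariate never hurts in-sample

    def test_fisher_se_matches_numerical_hessian(self):
        rng = np.random.default_rng(2)
        n = 200
        x = rng.standard_normal(n)
        y = (rng.random(n) < expit(0.5 + 0.8 * x)).astype(int)
        df = pd.DataFrame({"x": x, "response": y})
        m = fit_logistic(df, ["x"])

        def nll(theta):
            eta = theta[0] + theta[1] * x
            return -np.sum(y * eta - np.log1p(np.exp(eta)))

        res = minimize(nll, [0.0, 0.0], method="BFGS")
        hess = np.zeros((2, 2))
        eps = 1e-5
        for i in range(2):
            hess[i] = approx_fprime(res.x, lambda t: approx_fprime(t, nll, eps)[i], eps)
        se = np.sqrt(np.diag(np.linalg.inv((hess + hess.T) / 2)))
        assert m.bse["intercept"] == pytest.approx(se[0], abs=1e-4)
        assert m.bse["x"] == pytest.approx(se[1], abs=1e-4)

    def test_separation_flagged_not_silent(self):
        df = pd.DataFrame({"x": np.r_[np.zeros(10), np.ones(10)],
                           "response": np.r_[np.zeros(10), np.ones(10)].astype(int)})
        m = fit_logistic(df, ["x"])
        assert m.separation
        assert np.isfinite(lrt_pvalue(m))


class TestUnivariableScreen:
    def test_her2_lrt_p_matches_published_value(self):
        data = encode_clinical(fixture_clinical_group1()).dropna(subset=["her2"])
        p = univariable_screen(data, ["her2"]).loc["her2", "p"]
        assert round(p, 3) == 0.043

    def test_cd44_lrt_p_matches_published_value(self):
        data = encode_clinical(fixture_clinical_group2()).dropna(subset=["cd44"])
        p = univariable_screen(data, ["cd44"]).loc["cd44", "p"]
        assert round(p, 3) == 0.051

    def test_null_keep_rate_near_alpha(self):
        rng = np.random.default_rng(3)
        n, k = 400, 250
        df = pd.DataFrame(rng.standard_normal((n, k)),
                          columns=[f"f{i:03d}" for i in range(k)])
        df["response"] = rng.integers(0, 2, n)
        keep = univariable_screen(df, df.columns[:-1]).keep.mean()
        assert abs(keep - 0.2) < 3.2 * np.sqrt(0.2 * 0.8 / k)


class TestLassoSelect:
    def test_unpenalized_limit_selects_all(self):
        rng = np.random.default_rng(4)
        n = 300
        X = rng.standard_normal((n, 4))
        y = (rng.random(n) < expit(X @ [1.0, -1.0, 0.5, 0.8])).astype(int)
        df = pd.DataFrame(X, columns=list("abcd"))
        df["response"] = y
        out = lasso_select(df, list("abcd"), lambda_grid=np.array([1e-6]))
        assert out["selected"] == list("abcd")

    def test_full_shrinkage_empty_selection_flagged(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.standard_normal((100, 3)), columns=list("abc"))
        df["response"] = rng.integers(0, 2, 100)
        out = lasso_select(df, list("abc"), lambda_grid=np.array([1e4]))
        assert out["selected"] == [] and out["empty"]

    def test_selection_consistency_for_informative_pair(self):
        hits = 0
        runs = 25
        grid = np.geomspace(0.005, 1.0, 12)
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            n = 500
            X = rng.standard_normal((n, 7))
            eta = 1.5 * X[:, 0] - 1.5 * X[:, 1]
            y = (rng.random(n) < expit(eta)).astype(int)
            df = pd.DataFrame(X, columns=[f"v{i}" for i in range(7)])
            df["response"] = y
            sel = lasso_select(df, df.columns[:-1], lambda_grid=grid, seed=seed)["selected"]
            hits += ("v0" in sel) and ("v1" in sel)
        assert hits / runs >= 0.9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.standard_normal((150, 5)), columns=list("abcde"))
        df["response"] = rng.integers(0, 2, 150)
        s1 = lasso_select(df, list("abcde"), seed=11)
        s2 = lasso_select(df, list("abcde"), seed=11)
        assert s1["selected"] == s2["selected"] and s1["lambda"] == s2["lambda"]


@pytest.fixture(scope="module")
def cohort():
    spec = CohortSpec(n_patients=400, n_features=14,
                      beta={"her2": -2.0, "cd44": 1.5, "feat_b0_00": 0.7}, seed=7)
    return generate_cohort(spec)


class TestModelSuite:

    def test_twelve_models_with_union_structure(self, cohort):
        suite = build_model_suite(cohort.features, radiomic_covariates=("feat_b0_00",))
        assert tuple(suite) == MODEL_NAMES
        m1, m2, m3 = (set(suite[k].spec.covariates) for k in ("M1", "M2", "M3"))
        assert m3 == m1 | m2
        assert set(suite["M10"].spec.covariates) == m1 | {"her2", "cd44"}
        assert set(suite["M11"].spec.covariates) == m2 | {"her2", "cd44"}
        assert set(suite["M12"].spec.covariates) == m3 | {"her2", "cd44"}

    def test_markers_with_signal_improve_aic(self, cohort):
        suite = build_model_suite(cohort.features, radiomic_covariates=("feat_b0_00",))
        assert suite["M10"].aic < suite["M1"].aic

    def test_marker_missingness_drops_complete_cases_only(self, cohort):
        data = cohort.features.copy()
        data.loc[data.index[:25], "her2"] = np.nan
        suite = build_model_suite(data, radiomic_covariates=("feat_b0_00",))
        assert suite["M1"].n == len(data)
        assert suite["M4"].n == len(data) - 25
        assert suite["M7"].n == len(data)  # CD44 model unaffected by HER2 missingness
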