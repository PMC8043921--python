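"""Performance measures and bootstrap optimism correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.special import expit, logit

from petradiomics.models import fit_logistic
from petradiomics.validate import (
    MEASURES,
    auc,
    bootstrap_validate,
    brier,
    calibration_coefficients,
    calibration_curve,
    discrimination_slope,
    nagelkerke_r2,
)

from _oracles import auc_pairs_naive


class TestNagelkerke:
    def test_null_model_zero(self):
        assert nagelkerke_r2(-50.0, -50.0, 80) == 0.0

    def test_near_perfect_fit_approaches_one(self):
        # probabilities -> 0/1 drive the fitted LL to 0
        assert nagelkerke_r2(-60.0, -1e-9, 100) == pytest.approx(1.0, abs=1e-6)

    def test_toy_fit_matches_direct_likelihood_oracle(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([0, 1, 0, 1, 1, 1])
        df = pd.DataFrame({"x": x, "response": y})
        m = fit_logistic(df, ["x"])

        def nll(theta):
            eta = theta[0] + theta[1] * x
            return -np.sum(y * eta - np.log1p(np.exp(eta)))

        ll1 = -minimize(nll, [0.0, 0.0], method="BFGS").fun
        p0 = y.mean()
        ll0 = np.sum(y * np.log(p0) + (1 - y) * np.log(1 - p0))
        expected = (1 - np.exp(2 / 6 * (ll0 - ll1))) / (1 - np.exp(2 / 6 * ll0))
        assert nagelkerke_r2(m.llnull, m.llf, 6) == pytest.approx(expected, abs=1e-6)


class TestSimpleMeasures:
    def test_coin_flip_prediction_brier_quarter(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        assert brier(np.full(50, 0.5), y) == 0.25

    def test_perfect_prediction(self):
        y = np.array([0, 1, 0, 1, 1])
        p = y.astype(float)
        assert brier(p, y) == 0.0
        assert auc(p, y) == 1.0
        assert discrimination_slope(p, y) == 1.0

    def test_auc_with_ties_matches_pair_counting_oracle(self):
        p = np.array([0.2, 0.5, 0.5, 0.9])
        y = np.array([0, 0, 1, 1])
        assert auc(p, y) == pytest.approx(auc_pairs_naive(p, y), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_auc_oracle_and_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 20))
        p = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)  # force ties
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        a = auc(p, y)
        assert a == pytest.approx(auc_pairs_naive(p, y), abs=1e-12)
        assert auc(expit(5 * logit(p)), y) == pytest.approx(a, abs=1e-12)

    def test_ds_equals_class_mean_difference(self):
        rng = np.random.default_rng(1)
        p = rng.random(100)
        y = rng.integers(0, 2, 100)
        assert discrimination_slope(p, y) == pytest.approx(
            p[y == 1].mean() - p[y == 0].mean())

    def test_one_class_undefined(self):
        with pytest.raises(ValueError):
            auc(np.array([0.2, 0.8]), np.array([1, 1]))
        with pytest.raises(ValueError):
            discrimination_slope(np.array([0.2, 0.8]), np.array([0, 0]))


class TestCalibration:
    def test_well_calibrated_large_sample(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.05, 0.95, 100_000)
        y = (rng.random(100_000) < p).astype(int)
        a, b = calibration_coefficients(p, y)
        assert a == pytest.approx(0.0, abs=0.03)
        assert b == pytest.approx(1.0, abs=0.03)

    def test_overdispersed_logits_halve_the_slope(self):
        rng = np.random.default_rng(3)
        true_p = expit(rng.standard_normal(100_000))
        y = (rng.random(100_000) < true_p).astype(int)
        p_over = expit(2.0 * logit(true_p))
        _, b = calibration_coefficients(p_over, y)
        assert b == pytest.approx(0.5, abs=0.03)

    def test_shifted_logits_recovered_in_the_large(self):
        rng = np.random.default_rng(4)
        true_p = expit(-1.0 + rng.standard_normal(100_000))
        y = (rng.random(100_000) < true_p).astype(int)
        p_shift = expit(logit(true_p) + 0.5)
        a, _ = calibration_coefficients(p_shift, y)
        assert a == pytest.approx(-0.5, abs=0.05)

    def test_constant_predictions_undefined(self):
        with pytest.raises(ValueError, match="constant"):
            calibration_coefficients(np.full(20, 0.3), np.r_[np.ones(10), np.zeros(10)])

    def test_curve_single_point_on_diagonal_for_prevalence_prediction(self):
        y = np.r_[np.ones(20), np.zeros(60)]
        p = np.full(80, y.mean())
        binned = calibration_curve(p, y)
        assert len(binned) == 1
        assert binned.iloc[0]["p_mean"] == pytest.approx(binned.iloc[0]["obs_rate"])


def _noise_data(n=60, k=10, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.standard_normal((n, k)), columns=[f"x{i}" for i in range(k)])
    df["response"] = rng.integers(0, 2, n)
    return df


class TestBootstrapValidate:
    def test_null_model_has_no_optimism(self):
        df = _noise_data(n=96)
        m = fit_logistic(df, [])
        rep = bootstrap_validate(df, m, B=200, seed=0)
        for measure in ("nagelkerke_r2", "auc", "discrimination_slope"):
            assert abs(rep.optimism[measure]) < 1e-12
        assert abs(rep.optimism["brier"]) < 0.01

    def test_overfit_noise_model_optimism_is_substantial(self):
        df = _noise_data()
        m = fit_logistic(df, [f"x{i}" for i in range(10)])
        rep = bootstrap_validate(df, m, B=300, seed=1)
        assert rep.apparent["auc"] > 0.75
        assert rep.optimism["auc"] > 0.05
        assert rep.corrected["auc"] < rep.apparent["auc"] - 0.05

    def test_seed_contract_bit_identical(self):
        df = _noise_data(n=80, k=3, seed=2)
        m = fit_logistic(df, ["x0", "x1", "x2"])
        r1 = bootstrap_validate(df, m, B=50, seed=9)
        r2 = bootstrap_validate(df, m, B=50, seed=9)
        assert r1.optimism == r2.optimism and r1.corrected == r2.corrected

    def test_corrected_equals_apparent_minus_optimism(self):
        df = _noise_data(n=80, k=2, seed=3)
        m = fit_logistic(df, ["x0", "x1"])
        rep = bootstrap_validate(df, m, B=100, seed=4)
        for measure in MEASURES:
            assert rep.corrected[measure] == pytest.approx(
                rep.apparent[measure] - rep.optimism[measure])

    def test_doubling_B_barely_moves_corrected_auc(self):
        rng = np.random.default_rng(5)
        n = 120
        x = rng.standard_normal((n, 2))
        y = (rng.random(n) < expit(0.8 * x[:, 0])).astype(int)
        df = pd.DataFrame(x, columns=["x0", "x1"])
        df["response"] = y
        m = fit_logistic(df, ["x0", "x1"])
        r1 = bootstrap_validate(df, m, B=1000, seed=6)
        r2 = bootstrap_validate(df, m, B=2000, seed=6)
        assert abs(r1.corrected["auc"] - r2.corrected["auc"]) < 0.005

    def test_invalid_B_rejected(self):
        df = _noise_data(n=40, k=2, seed=7)
        m = fit_logistic(df, ["x0"])
        with pytest.raises(ValueError):
            bootstrap_validate(df, m, B=0)
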