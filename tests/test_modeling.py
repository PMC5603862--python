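"""Tests for LS-SVR fitting, validation statistics, and the applicability domain."""

import math

import numpy as np
import pytest
from scipy.linalg import solve as dense_solve

from qsarfs.errors import ConfigurationError, DataError
from qsarfs.modeling import (
    applicability_domain,
    fit_lssvr,
    grid_search_lssvr,
    leverage_threshold,
    loocv_rmse_lssvr,
    q2_loocv_lssvr,
    rbf_kernel,
    tropsha_roy_stats,
)


class TestRbfKernel:
    def test_identical_rows_give_one(self, rng):
        A = rng.standard_normal((4, 3))
        K = rbf_kernel(A, A, 2.0)
        np.testing.assert_allclose(np.diag(K), 1.0)

    def test_large_sigma2_flattens_to_one(self, rng):
        A = rng.standard_normal((4, 3))
        B = rng.standard_normal((5, 3))
        K = rbf_kernel(A, B, 1e12)
        np.testing.assert_allclose(K, 1.0, atol=1e-9)

    def test_matches_elementwise_oracle(self, rng):
        A = rng.standard_normal((5, 3))
        B = rng.standard_normal((4, 3))
        K = rbf_kernel(A, B, 1.7)
        for i in range(5):
            for j in range(4):
                d2 = float(np.sum((A[i] - B[j]) ** 2))
                assert K[i, j] == pytest.approx(math.exp(-d2 / 1.7), abs=1e-12)

    def test_nonpositive_sigma2_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            rbf_kernel(rng.standard_normal((2, 2)), rng.standard_normal((2, 2)), 0.0)


class TestFitLssvr:
    def test_huge_gamma_interpolates(self, rng):
        X = rng.standard_normal((8, 2))
        y = rng.standard_normal(8)
        model = fit_lssvr(X, y, gamma=1e9, sigma2=3.0)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-5)

    def test_constant_target(self, rng):
        X = rng.standard_normal((8, 2))
        model = fit_lssvr(X, np.full(8, 2.5), gamma=10.0, sigma2=1.0)
        assert model.bias == pytest.approx(2.5, abs=1e-6)
        np.testing.assert_allclose(model.alpha, 0.0, atol=1e-6)

    def test_matches_independent_block_solve(self, rng):
        X = rng.standard_normal((10, 3))
        y = rng.standard_normal(10)
        gamma, sigma2 = 12.0, 2.5
        model = fit_lssvr(X, y, gamma, sigma2)
        # independent oracle: assemble and solve the block system from scratch
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        K = np.exp(-d2 / sigma2)
        A = np.block([[np.zeros((1, 1)), np.ones((1, 10))],
                      [np.ones((10, 1)), K + np.eye(10) / gamma]])
        sol = dense_solve(A, np.concatenate([[0.0], y]))
        assert model.bias == pytest.approx(sol[0], abs=1e-8)
        np.testing.assert_allclose(model.alpha, sol[1:], atol=1e-8)

    def test_residual_identity_alpha_over_gamma(self, rng):
        X = rng.standard_normal((9, 2))
        y = rng.standard_normal(9)
        model = fit_lssvr(X, y, gamma=5.0, sigma2=1.5)
        np.testing.assert_allclose(y - model.predict(X), model.alpha / 5.0, atol=1e-9)

    def test_training_residual_decreasing_in_gamma(self, rng):
        X = rng.standard_normal((12, 3))
        y = rng.standard_normal(12)
        norms = []
        for gamma in (1.0, 10.0, 100.0, 1000.0, 1e5):
            model = fit_lssvr(X, y, gamma, sigma2=2.0)
            norms.append(np.linalg.norm(y - model.predict(X)))
        assert all(b <= a + 1e-9 for a, b in zip(norms, norms[1:]))

    def test_too_few_rows(self, rng):
        with pytest.raises(DataError):
            fit_lssvr(rng.standard_normal((2, 1)), np.zeros(2), 1.0, 1.0)


class TestGridSearch:
    def test_single_cell_grid(self, rng):
        X = rng.standard_normal((8, 2))
        y = rng.standard_normal(8)
        g, s, cv = grid_search_lssvr(X, y, np.array([3.0]), np.array([1.5]))
        assert (g, s) == (3.0, 1.5)
        assert cv == pytest.approx(loocv_rmse_lssvr(X, y, 3.0, 1.5))

    def test_argmin_contract(self, rng):
        X = rng.standard_normal((9, 2))
        y = X[:, 0] * 2.0 + 0.1 * rng.standard_normal(9)
        gammas = np.array([1.0, 50.0])
        sigmas = np.array([0.5, 5.0])
        g, s, cv = grid_search_lssvr(X, y, gammas, sigmas)
        for gg in gammas:
            for ss in sigmas:
                assert cv <= loocv_rmse_lssvr(X, y, float(gg), float(ss)) + 1e-12

    def test_sensible_pair_beats_degenerate_one(self, rng):
        X = rng.standard_normal((12, 2))
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1]
        g, s, _ = grid_search_lssvr(X, y, np.array([100.0, 1e-4]), np.array([2.0, 1e-6]))
        assert (g, s) == (100.0, 2.0)

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            grid_search_lssvr(rng.standard_normal((8, 2)), np.zeros(8), np.array([]), np.array([1.0]))


class TestTropshaRoyStats:
    def test_perfect_prediction(self, rng):
        y = rng.standard_normal(11) + 6.0
        rep = tropsha_roy_stats(y, y, q2_train=0.9)
        assert rep.rp2 == pytest.approx(1.0)
        assert rep.r0p2 == pytest.approx(1.0)
        assert rep.rm2 == pytest.approx(1.0)
        assert rep.k == pytest.approx(1.0) and rep.k_prime == pytest.approx(1.0)
        assert all(rep.passes.values())

    def test_doubled_prediction_fails_slope(self, rng):
        y = rng.standard_normal(11) + 6.0
        rep = tropsha_roy_stats(y, 2.0 * y, q2_train=0.9)
        assert rep.k == pytest.approx(0.5)
        assert rep.k_prime == pytest.approx(2.0)
        assert not rep.passes["slope"]

    def test_matches_formula_oracle(self, rng):
        y = rng.standard_normal(11) + 6.0
        yhat = y + 0.3 * rng.standard_normal(11)
        rep = tropsha_roy_stats(y, yhat, q2_train=0.8)
        # from-scratch formula evaluation
        r = np.corrcoef(y, yhat)[0, 1]
        rp2 = r * r
        k = np.sum(y * yhat) / np.sum(yhat**2)
        kp = np.sum(y * yhat) / np.sum(y**2)

        def r02(u, v):
            slope = np.sum(u * v) / np.sum(v * v)
            return 1 - np.sum((u - slope * v) ** 2) / np.sum((u - u.mean()) ** 2)

        r0 = r02(yhat, y)
        r0p = r02(y, yhat)
        assert rep.rp2 == pytest.approx(rp2, abs=1e-10)
        assert rep.k == pytest.approx(k, abs=1e-10)
        assert rep.k_prime == pytest.approx(kp, abs=1e-10)
        assert rep.r0p2 == pytest.approx(r0, abs=1e-10)
        assert rep.r0p2_prime == pytest.approx(r0p, abs=1e-10)
        assert rep.rm2 == pytest.approx(rp2 * (1 - np.sqrt(max(0.0, rp2 - r0))), abs=1e-10)
        assert rep.delta == pytest.approx((rp2 - r0) / rp2, abs=1e-10)

    def test_swap_symmetry(self, rng):
        y = rng.standard_normal(9) + 5.0
        yhat = y + 0.4 * rng.standard_normal(9)
        fwd = tropsha_roy_stats(y, yhat, q2_train=0.7)
        rev = tropsha_roy_stats(yhat, y, q2_train=0.7)
        assert fwd.k == pytest.approx(rev.k_prime)
        assert fwd.k_prime == pytest.approx(rev.k)
        assert fwd.r0p2 == pytest.approx(rev.r0p2_prime)
        assert fwd.r0p2_prime == pytest.approx(rev.r0p2)

    def test_pass_flags_recomputable_from_fields(self, rng):
        y = rng.standard_normal(10) + 6.0
        yhat = y + 0.5 * rng.standard_normal(10)
        rep = tropsha_roy_stats(y, yhat, q2_train=0.65)
        assert rep.passes["q2"] == (rep.q2 > 0.5)
        assert rep.passes["r2_pred"] == (rep.rp2 > 0.6)
        assert rep.passes["origin_offset"] == ((rep.delta < 0.1) or (rep.delta_prime < 0.1))
        assert rep.passes["slope"] == (
            (0.85 <= rep.k <= 1.15) or (0.85 <= rep.k_prime <= 1.15)
        )
        assert rep.passes["rm2"] == ((rep.rm2 > 0.5) and (rep.rm2_prime > 0.5))

    def test_anticorrelated_data_stays_finite(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        yhat = np.array([4.1, 2.9, 2.1, 0.8])  # anti-correlated
        rep = tropsha_roy_stats(y, yhat, q2_train=0.9)
        assert np.isfinite(rep.rm2) and np.isfinite(rep.rm2_prime)

    def test_negative_radicand_clamped_and_flagged(self):
        # rp2 - r0p2 >= 0 analytically (affine residuals never exceed
        # through-origin residuals), so the clamp guards rounding only
        from qsarfs.modeling import _rm2

        value, clamped = _rm2(0.9, 0.9 + 1e-15)
        assert clamped
        assert value == pytest.approx(0.9)

    def test_length_check(self):
        with pytest.raises(DataError):
            tropsha_roy_stats(np.zeros(3), np.zeros(4), 0.5)


class TestApplicabilityDomain:
    def test_published_threshold_arithmetic(self):
        h = leverage_threshold(8, 44)
        assert h == pytest.approx(3 * 8 / 44)
        assert math.floor(h * 100) / 100 == 0.54  # printed to two decimals

    def test_leverages_sum_to_p(self, rng):
        Xtr = rng.standard_normal((44, 8))
        Xte = rng.standard_normal((11, 8))
        ad = applicability_domain(Xtr, Xte, rng.standard_normal(44), rng.standard_normal(11))
        assert float(ad.leverages_train.sum()) == pytest.approx(8.0, abs=1e-8)
        assert np.all(ad.leverages_train > 0)
        assert np.all(ad.leverages_train <= 1.0 + 1e-12)

    def test_extrapolation_point_flagged(self, rng):
        Xtr = rng.standard_normal((30, 4))
        Xte = np.vstack([rng.standard_normal(4), np.full(4, 50.0)])
        ad = applicability_domain(
            Xtr, Xte, rng.standard_normal(30), np.zeros(2),
            test_ids=["ok", "far"],
        )
        assert ad.leverages_test[1] > ad.h_star
        assert "far" in ad.outliers

    def test_large_residual_flagged(self, rng):
        Xtr = rng.standard_normal((30, 4))
        res_tr = rng.standard_normal(30)
        res_te = np.array([0.0, 10.0 * res_tr.std(ddof=1)])
        ad = applicability_domain(
            Xtr, rng.standard_normal((2, 4)), res_tr, res_te, test_ids=["a", "b"]
        )
        assert "b" in ad.outliers

    def test_williams_frame_layout(self, rng):
        Xtr = rng.standard_normal((10, 3))
        Xte = rng.standard_normal((4, 3))
        ad = applicability_domain(Xtr, Xte, rng.standard_normal(10), rng.standard_normal(4))
        frame = ad.to_frame()
        assert list(frame.columns) == ["compound_id", "leverage", "std_residual", "set"]
        assert (frame["set"] == "train").sum() == 10
        assert (frame["set"] == "test").sum() == 4


class TestQ2:
    def test_q2_upper_bound(self, rng):
        X = rng.standard_normal((10, 2))
        y = X[:, 0] + 0.05 * rng.standard_normal(10)
        q2 = q2_loocv_lssvr(X, y, gamma=100.0, sigma2=5.0)
        assert q2 <= 1.0
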