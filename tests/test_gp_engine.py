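import numpy as np
import pytest
from scipy.stats import multivariate_normal

from bbgp import gp_engine
from bbgp.gp_engine import (
    assemble_covariance,
    fit_noise_model,
    fit_se_model,
    gp_predict,
    log_marginal_likelihood,
    se_covariance,
)


class TestSECovariance:
    def test_zero_lag_returns_signal_variance(self):
        K = se_covariance([3.0], [3.0], length_scale=5.0, signal_variance=0.05)
        assert K[0, 0] == pytest.approx(0.05)

    def test_lag_sqrt2_l_gives_exp_minus_one(self):
        ell = 4.0
        K = se_covariance([0.0], [ell * np.sqrt(2)], ell, 1.0)
        assert K[0, 0] == pytest.approx(np.exp(-1), rel=1e-12)

    def test_large_length_scale_constant_limit(self):
        t = np.array([0.0, 10.0, 60.0])
        K = se_covariance(t, t, length_scale=1e8, signal_variance=0.3)
        assert np.allclose(K, 0.3, atol=1e-10)

    def test_nonpositive_length_scale_rejected(self):
        with pytest.raises(ValueError):
            se_covariance([0.0], [1.0], 0.0, 1.0)


class TestAssembleCovariance:
    def test_kernel_absent_is_diagonal(self):
        C = assemble_covariance([0.0, 1.0], None, 0.0, [0.1, 0.2])
        assert np.allclose(C, np.diag([0.1, 0.2]))

    def test_scalar_sum(self):
        C = assemble_covariance([0.0], (2.0, 0.3), 0.2, [0.1])
        assert C[0, 0] == pytest.approx(0.6)

    def test_replicates_at_same_time_share_signal(self):
        C = assemble_covariance([0.0, 0.0], (5.0, 0.7), 0.1, [0.0, 0.0])
        assert C[0, 1] == pytest.approx(0.7)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            assemble_covariance([0.0, 1.0], None, 0.0, [0.1])


class TestLogMarginalLikelihood:
    @pytest.mark.parametrize(
        "y, C, expected",
        [
            ([0.0], [[0.5]], -0.5 * np.log(2 * np.pi * 0.5)),
            ([1.0], [[1.0]], -0.5 - 0.5 * np.log(2 * np.pi)),
            ([1.0, -1.0], np.diag([1.0, 1.0]), -1.0 - np.log(2 * np.pi)),
        ],
    )
    def test_univariate_and_independent_oracles(self, y, C, expected):
        assert log_marginal_likelihood(y, C) == pytest.approx(expected, abs=1e-9)

    def test_matches_dense_multivariate_normal(self, rng):
        """Cholesky-based LML equals a dense multivariate-normal logpdf."""
        for _ in range(25):
            J = int(rng.integers(2, 11))
            t = np.sort(rng.uniform(0, 60, J))
            C = assemble_covariance(
                t, (rng.uniform(2, 40), rng.uniform(0.01, 1)),
                rng.uniform(1e-4, 0.1), rng.uniform(1e-4, 0.05, J),
            )
            y = rng.normal(0, 0.3, J)
            expected = multivariate_normal(mean=np.zeros(J), cov=C).logpdf(y)
            assert log_marginal_likelihood(y, C) == pytest.approx(expected, abs=1e-8)

    def test_sign_flip_invariance(self, rng):
        t = np.arange(6.0)
        C = assemble_covariance(t, (3.0, 0.4), 0.05, np.full(6, 0.01))
        y = rng.normal(size=6)
        assert log_marginal_likelihood(y, C) == pytest.approx(
            log_marginal_likelihood(-y, C), abs=1e-12
        )


class TestPredict:
    def test_reverts_to_prior_far_from_data(self):
        t = np.array([0.0, 5.0, 10.0])
        kernel = (2.0, 0.5)
        C = assemble_covariance(t, kernel, 0.01, np.zeros(3))
        mean, cov = gp_predict([1000.0], t, [0.3, -0.1, 0.2], kernel, C)
        assert mean[0] == pytest.approx(0.0, abs=1e-10)
        assert cov[0, 0] == pytest.approx(0.5, abs=1e-10)

    def test_noise_free_interpolation(self):
        t = np.array([4.0])
        kernel = (3.0, 0.2)
        C = assemble_covariance(t, kernel, 0.0, np.zeros(1))
        mean, _ = gp_predict([4.0], t, [0.17], kernel, C)
        assert mean[0] == pytest.approx(0.17, rel=1e-9)

    def test_matches_conditional_gaussian_oracle(self, rng):
        """Random 4-point prediction equals the brute-force partitioned
        Gaussian conditional computed with dense inverses."""
        t = np.sort(rng.uniform(0, 60, 4))
        ts = np.linspace(-5, 65, 7)
        kernel = (rng.uniform(5, 30), rng.uniform(0.05, 0.5))
        fbb = rng.uniform(1e-4, 0.02, 4)
        C = assemble_covariance(t, kernel, 0.02, fbb)
        y = rng.normal(0, 0.3, 4)
        mean, cov = gp_predict(ts, t, y, kernel, C)
        Ks = se_covariance(ts, t, *kernel)
        Kss = se_covariance(ts, ts, *kernel)
        Cinv = np.linalg.inv(C)
        assert np.allclose(mean, Ks @ Cinv @ y, atol=1e-10)
        assert np.allclose(cov, Kss - Ks @ Cinv @ Ks.T, atol=1e-10)


class TestNoiseModelFit:
    def test_two_point_closed_form(self):
        fit = fit_noise_model([-1.0, 1.0], [0.0, 0.0])
        assert fit.noise_variance == pytest.approx(1.0, abs=1e-6)
        assert fit.log_ml == pytest.approx(-1.0 - np.log(2 * np.pi), abs=1e-6)

    def test_white_noise_mle_is_mean_square(self, rng):
        y = rng.normal(0, 0.4, 40)
        y = y - y.mean()
        fit = fit_noise_model(y, np.zeros(40))
        assert fit.noise_variance == pytest.approx(float(np.mean(y * y)), abs=1e-6)

    def test_equal_fbb_shifts_the_mle(self, rng):
        y = rng.normal(0, 0.5, 30)
        y = y - y.mean()
        c = 0.04
        fit = fit_noise_model(y, np.full(30, c))
        expected = max(float(np.mean(y * y)) - c, 0.0)
        assert fit.noise_variance == pytest.approx(expected, abs=1e-6)

    def test_huge_fbb_drives_noise_to_floor(self, rng):
        y = rng.normal(0, 0.05, 20)
        y = y - y.mean()
        fit = fit_noise_model(y, np.full(20, 50.0))
        assert fit.noise_variance <= 1e-6


class TestSEModelFit:
    def test_constant_data_matches_noise_model(self):
        t = np.array([0.0, 14, 28, 44, 60] * 3)
        y = np.zeros(t.size)
        fbb = np.full(t.size, 0.005)
        dep = fit_se_model(t, y, fbb)
        indep = fit_noise_model(y, fbb)
        assert abs(dep.log_ml - indep.log_ml) < 1e-6

    def test_nested_model_bound(self, rng):
        """With the independent optimum in the candidate set, the
        time-dependent maximum can never fall below it."""
        for _ in range(20):
            t = np.array([0.0, 14, 28, 44, 60] * 3)
            y = rng.normal(0, 0.1, t.size)
            y = y - y.mean()
            fbb = rng.uniform(1e-3, 1e-2, t.size)
            indep = fit_noise_model(y, fbb)
            dep = fit_se_model(
                t, y, fbb,
                extra_inits=[(14.0, gp_engine.VAR_FLOOR, indep.noise_variance)],
            )
            assert dep.log_ml - indep.log_ml >= -1e-6

    def test_recovers_length_scale_from_gp_draw(self, rng):
        """Median recovered length scale over repeated draws from a known
        GP stays within a factor of two of the truth."""
        t = np.array(sorted([0, 6, 14, 22, 28, 38, 44, 50, 60] * 5), dtype=float)
        true_l, true_sf2, true_sn2 = 15.0, 0.05, 1e-4
        K = se_covariance(t, t, true_l, true_sf2) + true_sn2 * np.eye(t.size)
        ls = []
        for _ in range(20):
            y = rng.multivariate_normal(np.zeros(t.size), K, method="cholesky")
            y = y - y.mean()
            fit = fit_se_model(t, y, np.zeros(t.size))
            ls.append(fit.length_scale)
        med = np.median(ls)
        assert true_l / 2 <= med <= true_l * 2

    def test_respects_length_scale_lower_bound(self, rng):
        t = np.array([0.0, 14, 28, 44, 60] * 5)
        y = rng.normal(0, 0.2, t.size)
        y = y - y.mean()
        fit = fit_se_model(t, y, np.full(t.size, 1e-3))
        assert fit.length_scale >= 14.0 - 1e-9
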