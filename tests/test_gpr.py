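"""Gaussian process regression: covariances, marginal likelihood, posterior."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from voltdiff.errors import DimensionMismatchError, InvalidInputError
from voltdiff.gpr import (
    Covariance,
    CovarianceSpec,
    covariance_matrix,
    gpr_predict,
    gpr_train,
    log_marginal_likelihood,
)
from voltdiff.gpr import _neg_lml_and_grad
from voltdiff.serialize import load_model, save_model

SQEXP = CovarianceSpec(Covariance.SQEXP, 1.3, 0.8, 0.05)


def dense_lml(X, y, cov):
    """Marginal likelihood via explicit determinant and inverse (oracle)."""
    S = covariance_matrix(X, X, cov, add_noise=True)
    resid = y - y.mean()
    m = len(y)
    return (
        -0.5 * math.log(np.linalg.det(S))
        - 0.5 * resid @ np.linalg.solve(S, resid)
        - 0.5 * m * math.log(2 * math.pi)
    )


class TestCovariances:
    def test_sqexp_at_zero_distance(self):
        x = np.array([[0.5, -1.0]])
        assert covariance_matrix(x, x, SQEXP)[0, 0] == pytest.approx(1.3)

    def test_linear_offset_at_origin(self):
        cov = CovarianceSpec(Covariance.LINEAR, 2.0)
        x = np.zeros((1, 3))
        assert covariance_matrix(x, x, cov)[0, 0] == pytest.approx(2.0)

    def test_noise_only_on_square_matrix(self):
        x = np.zeros((2, 2))
        z = np.zeros((3, 2))
        with pytest.raises(DimensionMismatchError):
            covariance_matrix(x, z, SQEXP, add_noise=True)

    def test_positive_definite_with_noise(self, rng):
        for _ in range(5):
            X = rng.normal(size=(6, 3))
            S = covariance_matrix(X, X, SQEXP, add_noise=True)
            np.linalg.cholesky(S)  # raises if not PD

    def test_parameter_validation(self):
        with pytest.raises(InvalidInputError):
            CovarianceSpec(Covariance.SQEXP, 1.0)  # missing length scale
        with pytest.raises(InvalidInputError):
            CovarianceSpec(Covariance.LINEAR, -1.0)


class TestMarginalLikelihood:
    def test_unit_scalar_case(self):
        """One point with unit residual and unit total variance:
        L = -1/2 - (1/2) log(2 pi)."""
        theta = np.log([0.5, 1.0, 0.5])  # sigma^2 + noise = 1
        neg, _ = _neg_lml_and_grad(theta, Covariance.SQEXP,
                                   np.zeros((1, 1)), np.array([1.0]),
                                   np.zeros((1, 1)))
        assert -neg == pytest.approx(-0.5 - 0.5 * math.log(2 * math.pi), abs=1e-12)

    def test_matches_dense_oracle(self, rng):
        for _ in range(5):
            X = rng.normal(size=(6, 2))
            y = rng.normal(size=6)
            assert log_marginal_likelihood(X, y, SQEXP) == pytest.approx(
                dense_lml(X, y, SQEXP), abs=1e-8
            )

    def test_matches_sklearn(self, rng):
        gp_mod = pytest.importorskip("sklearn.gaussian_process")
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

        X = rng.normal(size=(8, 2))
        y = rng.normal(size=8)
        resid = y - y.mean()
        kernel = ConstantKernel(1.3, "fixed") * RBF(0.8, "fixed") + WhiteKernel(0.05, "fixed")
        ref = gp_mod.GaussianProcessRegressor(kernel=kernel, optimizer=None, alpha=0.0)
        ref.fit(X, resid)
        assert log_marginal_likelihood(X, y, SQEXP) == pytest.approx(
            ref.log_marginal_likelihood(), abs=1e-8
        )

    def test_permutation_invariance(self, rng):
        X = rng.normal(size=(7, 3))
        y = rng.normal(size=7)
        perm = rng.permutation(7)
        assert log_marginal_likelihood(X, y, SQEXP) == pytest.approx(
            log_marginal_likelihood(X[perm], y[perm], SQEXP), abs=1e-10
        )

    def test_analytic_gradient_matches_finite_differences(self, rng):
        X = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        resid = y - y.mean()
        sqd = cdist(X, X, "sqeuclidean")
        for _ in range(10):
            theta = rng.uniform(-1.5, 1.0, size=3)
            _, grad = _neg_lml_and_grad(theta, Covariance.SQEXP, X, resid, sqd)
            for i in range(3):
                e = np.zeros(3)
                e[i] = 1e-6
                fp, _ = _neg_lml_and_grad(theta + e, Covariance.SQEXP, X, resid, sqd)
                fm, _ = _neg_lml_and_grad(theta - e, Covariance.SQEXP, X, resid, sqd)
                fd = (fp - fm) / 2e-6
                assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)


class TestTraining:
    def test_optimum_beats_every_start(self, rng):
        """The returned likelihood dominates the value at each initialization."""
        X = rng.normal(size=(20, 2))
        y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=20)
        model = gpr_train(X, y, Covariance.SQEXP, n_starts=5, seed=4)
        resid = y - y.mean()
        sqd = cdist(X, X, "sqeuclidean")
        var_y = float(resid.var())
        med = float(np.median(sqd[sqd > 0]))
        check_rng = np.random.default_rng(4)
        for _ in range(5):
            theta0 = np.array([
                math.log(var_y) + check_rng.uniform(-1, 1),
                math.log(math.sqrt(med)) + check_rng.uniform(-1.5, 1.5),
                math.log(var_y) + check_rng.uniform(-12, -2),
            ])
            f0, _ = _neg_lml_and_grad(theta0, Covariance.SQEXP, X, resid, sqd)
            assert model.log_marginal >= -f0 - 1e-9

    def test_parameter_recovery_from_known_gp(self):
        """Data drawn from a known squared-exponential GP: the recovered
        log-hyperparameters land within 0.5 nats (median over replicates)."""
        true = CovarianceSpec(Covariance.SQEXP, 1.0, 1.0, 0.01)
        errors = []
        for rep in range(8):
            rng = np.random.default_rng(100 + rep)
            X = rng.uniform(-4, 4, size=(60, 1))
            S = covariance_matrix(X, X, true, add_noise=True)
            y = np.linalg.cholesky(S) @ rng.normal(size=60)
            model = gpr_train(X, y, Covariance.SQEXP, n_starts=4, seed=rep)
            errors.append(
                abs(math.log(model.cov.signal_variance))
                + abs(math.log(model.cov.length_scale))
            )
        assert np.median(errors) < 1.0  # 0.5 nats per parameter

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        a = gpr_train(X, y, Covariance.SQEXP, seed=9)
        b = gpr_train(X, y, Covariance.SQEXP, seed=9)
        assert a.cov == b.cov


class TestPrediction:
    def test_noiseless_interpolation(self, rng):
        X = rng.uniform(-2, 2, size=(12, 1))
        y = np.sin(X[:, 0])
        from voltdiff.gpr import GPModel, _chol_with_jitter
        import scipy.linalg

        cov = CovarianceSpec(Covariance.SQEXP, 1.0, 1.0, 0.0)
        S = covariance_matrix(X, X, cov, add_noise=True)
        L, _ = _chol_with_jitter(S)
        resid = y - y.mean()
        model = GPModel(cov, X, float(y.mean()), resid, L,
                        scipy.linalg.cho_solve((L, True), resid), 0.0)
        mean, var = gpr_predict(model, X)
        np.testing.assert_allclose(mean, y, atol=1e-6)
        assert var.max() <= 1e-6

    def test_posterior_mean_equals_kernel_ridge(self, rng):
        """With noise sigma_n^2 the posterior mean is ridge regression with
        penalty sigma_n^2 on the centered targets."""
        X = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        cov = CovarianceSpec(Covariance.SQEXP, 1.5, 1.2, 0.3)
        from voltdiff.gpr import GPModel, _chol_with_jitter
        import scipy.linalg

        S = covariance_matrix(X, X, cov, add_noise=True)
        L, _ = _chol_with_jitter(S)
        resid = y - y.mean()
        model = GPModel(cov, X, float(y.mean()), resid, L,
                        scipy.linalg.cho_solve((L, True), resid), 0.0)
        Z = rng.normal(size=(6, 2))
        mean, _ = gpr_predict(model, Z)
        K = covariance_matrix(X, X, cov)
        Ks = covariance_matrix(X, Z, cov)
        ridge = y.mean() + Ks.T @ np.linalg.solve(
            K + cov.noise_variance * np.eye(10), resid
        )
        np.testing.assert_allclose(mean, ridge, atol=1e-8)

    def test_far_field_reverts_to_prior(self, rng):
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        model = gpr_train(X, y, Covariance.SQEXP, seed=1)
        mean, var = gpr_predict(model, np.full((1, 2), 1e3))
        assert mean[0] == pytest.approx(model.target_mean, abs=1e-6)
        assert var[0] == pytest.approx(model.cov.signal_variance, rel=1e-6)

    def test_variance_nonnegative_and_shrinks_with_data(self, rng):
        """Adding a training point never increases posterior variance."""
        X = rng.uniform(-3, 3, size=(20, 1))
        y = np.sin(X[:, 0]) + 0.05 * rng.normal(size=20)
        query = np.array([[0.37]])
        cov = CovarianceSpec(Covariance.SQEXP, 1.0, 0.8, 0.01)
        from voltdiff.gpr import GPModel, _chol_with_jitter
        import scipy.linalg

        variances = []
        for n in (5, 10, 20):
            S = covariance_matrix(X[:n], X[:n], cov, add_noise=True)
            L, _ = _chol_with_jitter(S)
            resid = y[:n] - y[:n].mean()
            model = GPModel(cov, X[:n], float(y[:n].mean()), resid, L,
                            scipy.linalg.cho_solve((L, True), resid), 0.0)
            variances.append(gpr_predict(model, query)[1][0])
        assert all(v >= 0.0 for v in variances)
        assert variances[0] >= variances[1] >= variances[2]

    def test_serialization_round_trip(self, rng, tmp_path):
        X = rng.normal(size=(12, 2))
        y = rng.normal(size=12)
        model = gpr_train(X, y, Covariance.SQEXP, seed=0)
        path = tmp_path / "gp.json"
        save_model(model, path)
        back = load_model(path)
        Z = rng.normal(size=(5, 2))
        np.testing.assert_array_equal(gpr_predict(back, Z)[0], gpr_predict(model, Z)[0])
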