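import numpy as np
import pandas as pd
import pytest

from causalfoodq.dataset import Dataset, continuous
from causalfoodq.selection import (
    elastic_net_fit,
    lambda_max,
    pca_variance,
    select_features_cv,
    standardize,
)


def _dataset(arrays: dict) -> Dataset:
    df = pd.DataFrame(arrays)
    return Dataset(df, {c: continuous() for c in df.columns})


class TestStandardize:
    def test_closed_form(self):
        std = standardize(_dataset({"x": [1.0, 2.0, 3.0]}))
        assert std.dataset.df["x"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        ds = _dataset({"x": rng.normal(size=100)})
        once = standardize(ds).dataset
        twice = standardize(once).dataset
        assert np.allclose(once.df["x"], twice.df["x"], atol=1e-12)

    def test_constant_column_is_explicit_error(self):
        with pytest.raises(ValueError, match="x"):
            standardize(_dataset({"x": [2.0, 2.0, 2.0]}))

    def test_back_mapping(self):
        std = standardize(_dataset({"x": [1.0, 2.0, 3.0]}))
        assert std.inverse("x", np.array([-1.0, 0.0, 1.0])) == pytest.approx(
            [1.0, 2.0, 3.0]
        )


def _soft_threshold(b, lam):
    return np.sign(b) * np.maximum(np.abs(b) - lam, 0.0)


class TestElasticNet:
    def test_zero_penalty_equals_least_squares(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 5))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 3.0]) + rng.normal(size=200)
        fit = elastic_net_fit(X, y, lam=0.0, alpha=1.0)
        X1 = np.column_stack([np.ones(200), X])
        beta_ols = np.linalg.lstsq(X1, y, rcond=None)[0][1:]
        assert np.allclose(fit.beta.to_numpy(), beta_ols, atol=1e-6)

    def test_lambda_max_zeroes_everything(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 8))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = X @ rng.normal(size=8) + rng.normal(size=300)
        lmax = lambda_max(X, y, alpha=1.0)
        fit = elastic_net_fit(X, y, lam=lmax * 1.0001, alpha=1.0)
        assert fit.selected == ()
        # just below lambda_max at least one coefficient becomes active
        fit2 = elastic_net_fit(X, y, lam=lmax * 0.95, alpha=1.0)
        assert len(fit2.selected) >= 1

    @pytest.mark.parametrize("lam", [0.05, 0.2, 0.5])
    def test_orthonormal_soft_threshold(self, lam):
        # on an orthonormal design the lasso is the soft-thresholded OLS
        rng = np.random.default_rng(3)
        n, p = 400, 6
        raw = rng.normal(size=(n, p))
        Q, _ = np.linalg.qr(raw - raw.mean(axis=0))  # zero-mean orthonormal columns
        X = Q * np.sqrt(n)  # columns with X_j'X_j = n
        beta = np.array([1.0, -0.6, 0.3, 0.1, 0.0, -0.05])
        y = X @ beta + rng.normal(size=n) * 0.3
        fit = elastic_net_fit(X, y, lam=lam, alpha=1.0)
        beta_ols = X.T @ (y - y.mean()) / n
        assert np.allclose(fit.beta.to_numpy(), _soft_threshold(beta_ols, lam), atol=1e-6)

    def test_l1_norm_monotone_in_lambda_orthonormal(self):
        rng = np.random.default_rng(4)
        n, p = 400, 5
        Q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        X = Q * np.sqrt(n)
        y = X @ rng.normal(size=p) + rng.normal(size=n) * 0.5
        lams = np.geomspace(1e-3, 1.0, 20)
        norms = [
            np.abs(elastic_net_fit(X, y, lam=l, alpha=1.0).beta).sum() for l in lams
        ]
        assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))

    def test_kkt_conditions_at_solution(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(500, 10))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = X[:, 0] * 1.0 - X[:, 1] * 0.5 + rng.normal(size=500)
        lam, alpha = 0.1, 1.0
        fit = elastic_net_fit(X, y, lam=lam, alpha=alpha)
        resid = y - fit.intercept - X @ fit.beta.to_numpy()
        grad = X.T @ resid / len(y)
        inactive = fit.beta.to_numpy() == 0
        assert np.all(np.abs(grad[inactive]) <= lam * alpha + 1e-6)

    def test_nonfinite_values_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            elastic_net_fit(np.array([[1.0], [np.inf]]), np.array([0.0, 1.0]), 0.1, 1.0)


class TestSelectFeaturesCV:
    def test_pure_noise_explains_little(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(300, 20))
        y = rng.normal(size=300)
        fit, r2 = select_features_cv(X, y, alpha=0.5, n_folds=5, seed=0)
        assert len(fit.selected) == 0 or r2 < 0.1

    def test_fewer_rows_than_folds_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            select_features_cv(np.zeros((3, 2)), np.zeros(3), n_folds=5)

    def test_cv_table_populated(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(100, 5))
        y = X[:, 0] + rng.normal(size=100)
        fit, _ = select_features_cv(X, y, n_folds=5, n_lambdas=30, seed=1)
        assert len(fit.cv_table) == 30
        assert fit.cv_table["cv_error"].notna().all()


class TestPCAVariance:
    def test_spherical_case(self):
        rng = np.random.default_rng(8)
        ds = _dataset({f"x{i}": rng.normal(size=4000) for i in range(11)})
        out = pca_variance(ds, use_correlation=True)
        assert out.share(3) == pytest.approx(3 / 11, abs=0.02)
        assert out.cumulative[-1] == pytest.approx(1.0)

    def test_planted_eigenvalues(self):
        # covariance with eigenvalues (4, 1, 1): leading share 4/6
        rng = np.random.default_rng(9)
        z = rng.normal(size=(60_000, 3))
        L = np.diag(np.sqrt([4.0, 1.0, 1.0]))
        X = z @ L
        ds = _dataset({f"x{i}": X[:, i] for i in range(3)})
        out = pca_variance(ds, use_correlation=False)
        assert out.share(1) == pytest.approx(4 / 6, abs=0.02)

    def test_matches_bruteforce_eigensolver(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            A = rng.normal(size=(5, 5))
            cov = A @ A.T
            X = rng.multivariate_normal(np.zeros(5), cov, size=500)
            ds = _dataset({f"x{i}": X[:, i] for i in range(5)})
            out = pca_variance(ds, use_correlation=False)
            want = np.sort(np.linalg.eigvals(ds.to_numeric().cov().to_numpy()).real)[::-1]
            assert np.allclose(out.eigenvalues, want, atol=1e-8)

    def test_rank_deficiency_tolerated(self):
        x = np.random.default_rng(11).normal(size=200)
        ds = _dataset({"a": x, "b": 2 * x, "c": np.random.default_rng(12).normal(size=200)})
        out = pca_variance(ds, use_correlation=False)
        assert out.eigenvalues.min() >= 0
        assert out.cumulative[-1] == pytest.approx(1.0)
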