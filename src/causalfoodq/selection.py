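"""Elastic-net feature screening and PCA variance summaries.

Wide food-quality tables (tens of collinear physicochemical assays) are
first reduced to a small set of key predictors by the elastic net: the
penalized least-squares objective

    (1/2n) ||y - b0 - X beta||^2
        + lambda * [ alpha ||beta||_1 + (1 - alpha)/2 ||beta||_2^2 ]

with L1 mixing fraction ``alpha`` in [0, 1] (alpha = 1 is the LASSO).
The 1/(2n) convention makes lambda comparable across sample sizes.  The
penalty weight is chosen by K-fold cross-validation over a log-spaced
grid descending from lambda_max, the smallest penalty that zeroes every
coefficient.  The numerical solver is scikit-learn's coordinate descent;
the surrounding contracts (standardization, lambda grid, CV selection,
KKT checks in the tests) are owned here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold

from .dataset import Dataset

__all__ = [
    "Standardization",
    "standardize",
    "ElasticNetFit",
    "elastic_net_fit",
    "lambda_max",
    "select_features_cv",
    "PCASummary",
    "pca_variance",
]


@dataclass(frozen=True)
class Standardization:
    """A standardized dataset plus the transform parameters for back-mapping."""

    dataset: Dataset
    means: pd.Series
    sds: pd.Series

    def inverse(self, column: str, values: np.ndarray) -> np.ndarray:
        return np.asarray(values) * self.sds[column] + self.means[column]


def standardize(data: Dataset, columns: Sequence[str] | None = None) -> Standardization:
    """Center and scale columns to mean 0, sample sd 1 (n-1 denominator).

    Ordinal/binary columns are coerced to numeric codes first.  A
    zero-variance column is an explicit error, never a silent NaN.
    """
    cols = list(columns) if columns is not None else list(data.columns)
    num = data.to_numeric(cols)
    means = num.mean()
    sds = num.std(ddof=1)
    zero = sds[sds == 0].index.tolist()
    if zero:
        raise ValueError(f"cannot standardize zero-variance column(s) {zero}")
    out = (num - means) / sds
    df = data.df.copy()
    for c in cols:
        df[c] = out[c]
    kinds = dict(data.kinds)
    from .dataset import continuous as _cont

    for c in cols:
        kinds[c] = _cont()
    return Standardization(
        dataset=Dataset(df, kinds, dict(data.provenance)), means=means, sds=sds
    )


@dataclass
class ElasticNetFit:
    """A fitted elastic net: penalty, coefficients and the CV table."""

    lam: float
    alpha: float
    beta: pd.Series
    intercept: float
    cv_table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["lambda", "cv_error", "se"])
    )

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")

    @property
    def selected(self) -> tuple[str, ...]:
        return tuple(self.beta.index[self.beta != 0.0])


def _as_xy(
    X: pd.DataFrame | np.ndarray, y: pd.Series | np.ndarray
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xa.shape[1])]
    ya = np.asarray(y, dtype=float).ravel()
    if not (np.isfinite(Xa).all() and np.isfinite(ya).all()):
        raise ValueError("non-finite values in predictors or response")
    return Xa, ya, names


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest penalty zeroing all coefficients: max_j |X_j' (y - ybar)| / (n alpha)."""
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    n = len(ya)
    corr = np.abs(Xa.T @ (ya - ya.mean())) / n
    return float(corr.max() / max(alpha, 1e-3))


def elastic_net_fit(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    lam: float,
    alpha: float,
    tol: float = 1e-8,
) -> ElasticNetFit:
    """Solve the elastic-net problem at a single penalty.

    ``lam`` is the total penalty weight and ``alpha`` the L1 fraction; at
    lam = 0 the fit reduces to ordinary least squares.
    """
    Xa, ya, names = _as_xy(X, y)
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if lam == 0.0:
        X1 = np.column_stack([np.ones(len(ya)), Xa])
        coef = np.linalg.lstsq(X1, ya, rcond=None)[0]
        beta, b0 = coef[1:], float(coef[0])
    else:
        model = ElasticNet(
            alpha=lam, l1_ratio=alpha, fit_intercept=True, tol=tol, max_iter=100_000
        )
        model.fit(Xa, ya)
        beta, b0 = model.coef_, float(model.intercept_)
    return ElasticNetFit(
        lam=float(lam), alpha=float(alpha), beta=pd.Series(beta, index=names), intercept=b0
    )


def select_features_cv(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    alpha: float = 0.5,
    n_folds: int = 10,
    lambda_grid: Sequence[float] | None = None,
    n_lambdas: int = 100,
    seed: int = 0,
) -> tuple[ElasticNetFit, float]:
    """Choose lambda by K-fold CV, refit on all rows, report R² of the pick.

    The grid defaults to ``n_lambdas`` log-spaced values descending four
    decades from lambda_max.  The winning lambda minimizes the mean CV
    squared error (no one-SE rule); ``variance_explained`` is the R² of an
    unpenalized OLS refit on the selected predictors.
    """
    Xa, ya, names = _as_xy(X, y)
    n = len(ya)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n < n_folds:
        raise ValueError(f"fewer rows ({n}) than folds ({n_folds})")
    if lambda_grid is None:
        lmax = lambda_max(Xa, ya, alpha)
        lambda_grid = np.geomspace(lmax, lmax * 1e-4, n_lambdas)
    grid = np.sort(np.asarray(list(lambda_grid), dtype=float))[::-1]

    folds = list(KFold(n_folds, shuffle=True, random_state=seed).split(Xa))
    sq_errors = np.zeros((len(grid), n))
    for train, test in folds:
        model = ElasticNet(
            alpha=grid[0], l1_ratio=alpha, fit_intercept=True,
            warm_start=True, tol=1e-6, max_iter=50_000,
        )
        for i, lam in enumerate(grid):
            model.set_params(alpha=lam)
            model.fit(Xa[train], ya[train])
            pred = model.predict(Xa[test])
            sq_errors[i, test] = (ya[test] - pred) ** 2
    cv_mean = sq_errors.mean(axis=1)
    cv_se = sq_errors.std(axis=1, ddof=1) / np.sqrt(n)
    best = int(np.argmin(cv_mean))

    fit = elastic_net_fit(X, y, float(grid[best]), alpha)
    fit.cv_table = pd.DataFrame(
        {"lambda": grid, "cv_error": cv_mean, "se": cv_se}
    )
    selected = list(fit.selected)
    if selected:
        idx = [names.index(c) for c in selected]
        X1 = np.column_stack([np.ones(n), Xa[:, idx]])
        coef = np.linalg.lstsq(X1, ya, rcond=None)[0]
        resid = ya - X1 @ coef
        r2 = 1.0 - float(resid @ resid) / float(((ya - ya.mean()) ** 2).sum())
    else:
        r2 = 0.0
    return fit, r2


@dataclass(frozen=True)
class PCASummary:
    """Eigenvalues (descending) and cumulative variance shares."""

    eigenvalues: np.ndarray
    cumulative: np.ndarray  # cumulative variance fraction per component count

    def share(self, k: int) -> float:
        return float(self.cumulative[k - 1])


def pca_variance(data: Dataset, use_correlation: bool = True,
                 columns: Sequence[str] | None = None) -> PCASummary:
    """Eigen-decomposition of the covariance (or correlation) matrix.

    Rank deficiency is tolerated: zero eigenvalues simply contribute
    nothing to the cumulative share.
    """
    cols = list(columns) if columns is not None else list(data.continuous_columns())
    if len(cols) < 2:
        raise ValueError("need at least 2 continuous columns")
    num = data.to_numeric(cols)
    mat = num.corr().to_numpy() if use_correlation else num.cov().to_numpy()
    eig = np.linalg.eigvalsh(mat)[::-1]
    eig = np.clip(eig, 0.0, None)
    total = eig.sum()
    cumulative = np.cumsum(eig) / (total if total > 0 else 1.0)
    return PCASummary(eigenvalues=eig, cumulative=cumulative)
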