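"""Double machine learning for the average causal effect.

A structure-free validation route: instead of committing to a DAG, the
total ACE of a treatment on an outcome is estimated from residuals.  Both
the outcome and the treatment are regressed flexibly on the covariates;
the effect is the ratio

    theta = Cov(resid_outcome, resid_treatment) / Var(resid_treatment)

i.e. the partially linear residual-on-residual slope.  Nuisance
regressions are cross-fitted: rows are split into K folds and each row's
prediction comes from models trained on the other folds, which removes
the own-observation overfitting bias that plagues plug-in versions of the
same ratio (``n_folds=1`` reproduces the naive plug-in for comparison).

When all variables are standardized beforehand, theta is the "relative
factor" scale used to rank predictors of quality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold

from .dataset import Dataset

__all__ = [
    "DMLResult",
    "LinearDetrendedForest",
    "default_learner",
    "crossfit_residuals",
    "dml_ace",
]


class DegeneracyError(ValueError):
    """Treatment residual variance ~ 0: treatment fully explained by covariates."""


class LinearDetrendedForest(BaseEstimator, RegressorMixin):
    """OLS plus a random forest on the OLS residuals.

    Physicochemical covariate relationships are dominated by linear
    trends with milder nonlinear structure on top.  Fitting the linear
    component exactly (at the parametric rate) and letting the forest
    absorb only what is left keeps the nuisance-estimation bias of the
    residual-ratio estimator small, where a pure forest underfits strong
    linear signal.
    """

    def __init__(self, n_estimators: int = 100, min_samples_leaf: int = 25,
                 random_state: int = 0):
        self.n_estimators = n_estimators
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def fit(self, X, y):
        self.linear_ = LinearRegression().fit(X, y)
        resid = y - self.linear_.predict(X)
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_estimators,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state,
            n_jobs=1,
        ).fit(X, resid)
        return self

    def predict(self, X):
        return self.linear_.predict(X) + self.forest_.predict(X)


def default_learner(seed: int = 0):
    """Default nuisance learner: a linear-detrended 100-tree forest."""
    return LinearDetrendedForest(random_state=seed)


def _resolve_learner(spec, seed: int):
    if spec is None:
        return default_learner(seed)
    if spec == "rf":  # plain bagged-tree forest
        return RandomForestRegressor(
            n_estimators=500, min_samples_leaf=5, random_state=seed, n_jobs=1
        )
    if spec == "linear":
        return LinearRegression()
    model = clone(spec)
    if "random_state" in model.get_params():
        model.set_params(random_state=seed)
    return model


def crossfit_residuals(
    data: Dataset,
    target: str,
    covariates: Sequence[str],
    learner=None,
    n_folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-fold residuals of ``target`` regressed on ``covariates``.

    Residuals are centered to mean zero.  With ``n_folds=1`` the learner
    is fit and evaluated on all rows (the naive plug-in).
    """
    if target in covariates:
        raise ValueError("covariates must exclude the target")
    num = data.to_numeric([target, *covariates])
    y = num[target].to_numpy()
    n = len(y)
    if covariates:
        X = num[list(covariates)].to_numpy()
    else:
        return y - y.mean()
    if n_folds == 1:
        model = _resolve_learner(learner, seed)
        model.fit(X, y)
        resid = y - model.predict(X)
        return resid - resid.mean()
    if n_folds < 1:
        raise ValueError("n_folds must be >= 1")
    if n // n_folds < 5:
        raise ValueError("folds would have fewer than 5 rows")
    resid = np.empty(n)
    for k, (train, test) in enumerate(
        KFold(n_folds, shuffle=True, random_state=seed).split(X)
    ):
        model = _resolve_learner(learner, seed + k)
        model.fit(X[train], y[train])
        resid[test] = y[test] - model.predict(X[test])
    return resid - resid.mean()


@dataclass
class DMLResult:
    """Cross-fitted residual-ratio ACE with influence-function uncertainty."""

    treatment: str
    outcome: str
    theta: float
    se: float
    n_folds: int
    resid_outcome: np.ndarray
    resid_treatment: np.ndarray
    learner: str

    @property
    def n(self) -> int:
        return len(self.resid_outcome)


def dml_ace(
    data: Dataset,
    treatment: str,
    outcome: str,
    covariates: Sequence[str] | None = None,
    learner=None,
    n_folds: int = 5,
    seed: int = 0,
    standardize: bool = True,
    repeats: int = 1,
) -> DMLResult:
    """Residual-ratio ACE of ``treatment`` on ``outcome``.

    ``covariates`` defaults to every other column (the total-effect
    convention for per-variable effect rankings).  The standard error
    comes from the influence function of the partially linear estimator:
    psi_i = (rY_i - theta rT_i) rT_i / E[rT^2].  With ``repeats > 1`` the
    whole cross-fit is repeated on fresh fold splits and the median theta
    (with its split's se) is reported.
    """
    if covariates is None:
        covariates = [c for c in data.columns if c not in (treatment, outcome)]
    covariates = list(covariates)
    if treatment in covariates or outcome in covariates:
        raise ValueError("covariates must exclude treatment and outcome")

    work = data
    if standardize:
        from .selection import standardize as _std

        work = _std(data, [treatment, outcome, *covariates]).dataset

    results = []
    for r in range(repeats):
        split_seed = seed + 1000 * r
        r_t = crossfit_residuals(
            work, treatment, covariates, learner, n_folds, split_seed
        )
        r_y = crossfit_residuals(
            work, outcome, covariates, learner, n_folds, split_seed
        )
        var_t = float(r_t @ r_t) / len(r_t)
        if var_t < 1e-8:
            raise DegeneracyError(
                f"treatment {treatment!r} is fully explained by the covariates"
            )
        theta = float(r_y @ r_t) / float(r_t @ r_t)
        psi = (r_y - theta * r_t) * r_t / var_t
        se = float(psi.std(ddof=1) / np.sqrt(len(psi)))
        results.append((theta, se, r_y, r_t))
    results.sort(key=lambda t: t[0])
    theta, se, r_y, r_t = results[len(results) // 2]
    if learner is None:
        learner_name = "linear-detrended-forest"
    elif isinstance(learner, str):
        learner_name = learner
    else:
        learner_name = type(learner).__name__
    return DMLResult(
        treatment=treatment,
        outcome=outcome,
        theta=theta,
        se=se,
        n_folds=n_folds,
        resid_outcome=r_y,
        resid_treatment=r_t,
        learner=learner_name,
    )
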