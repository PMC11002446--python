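"""Bagged-tree predictive models with out-of-bag evaluation.

The predictive baseline for quality: an ensemble of decision trees, each
fit to a bootstrap resample of the rows with ``mtry`` candidate variables
per split (a random forest).  Out-of-bag (OOB) evaluation scores each row
using only the trees whose bootstrap excluded it — an internal,
nearly-unbiased stand-in for cross-validation.  The tree learner itself
is scikit-learn's; the bootstrap bookkeeping and the OOB metrics are
implemented and verified here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier, BaggingRegressor
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .dataset import CONTINUOUS, Dataset

__all__ = ["ForestModel", "fit_forest", "oob_metrics"]


@dataclass
class ForestModel:
    """A fitted bagged-tree ensemble plus its OOB bookkeeping."""

    task: str  # "regression" | "classification"
    target: str
    predictors: tuple[str, ...]
    n_trees: int
    mtry: int
    ensemble: object
    bootstrap_indices: list[np.ndarray]
    oob_prediction: np.ndarray  # NaN (or None labels) where never OOB
    oob_mask: np.ndarray  # rows with at least one OOB tree
    classes: tuple | None = None


def _resolve_task(data: Dataset, target: str, task: str) -> str:
    if task in ("regression", "classification"):
        return task
    if task != "auto":
        raise ValueError(f"unknown task {task!r}")
    return (
        "regression" if data.kind_of(target).kind == CONTINUOUS else "classification"
    )


def fit_forest(
    data: Dataset,
    target: str,
    n_trees: int = 500,
    mtry: int | None = None,
    task: str = "auto",
    seed: int = 0,
    min_samples_leaf: int = 5,
    predictors: Sequence[str] | None = None,
) -> ForestModel:
    """Fit a random forest of ``n_trees`` bootstrap trees.

    ``mtry`` is the number of candidate variables per split (default:
    p/3 for regression, sqrt(p) for classification, at least 1).  The
    returned model stores every tree's bootstrap row indices, from which
    OOB predictions are computed: regression averages the OOB trees'
    predictions, classification majority-votes them.
    """
    task = _resolve_task(data, target, task)
    if predictors is None:
        predictors = [c for c in data.columns if c != target]
    predictors = list(predictors)
    if not predictors:
        raise ValueError("no predictor columns")
    num = data.to_numeric(predictors)
    X = num.to_numpy()
    n, p = X.shape
    if mtry is None:
        mtry = max(1, p // 3) if task == "regression" else max(1, int(np.sqrt(p)))
    if mtry > p:
        raise ValueError(f"mtry ({mtry}) exceeds the number of predictors ({p})")

    if task == "regression":
        y = data.to_numeric([target])[target].to_numpy()
        base = DecisionTreeRegressor(max_features=mtry, min_samples_leaf=min_samples_leaf)
        bagger = BaggingRegressor(
            estimator=base, n_estimators=n_trees, bootstrap=True, random_state=seed
        )
    else:
        y = data.df[target].astype(str).to_numpy()
        if len(np.unique(y)) < 2:
            raise ValueError("classification target has a single class")
        base = DecisionTreeClassifier(max_features=mtry, min_samples_leaf=min_samples_leaf)
        bagger = BaggingClassifier(
            estimator=base, n_estimators=n_trees, bootstrap=True, random_state=seed
        )
    bagger.fit(X, y)
    boot = [np.asarray(idx) for idx in bagger.estimators_samples_]

    # OOB predictions: only trees whose bootstrap excluded the row
    in_bag = np.zeros((n_trees, n), dtype=bool)
    for t, idx in enumerate(boot):
        in_bag[t, idx] = True
    oob_mask = ~in_bag.all(axis=0)
    if task == "regression":
        preds = np.stack([tree.predict(X) for tree in bagger.estimators_])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sums = np.where(~in_bag, preds, 0.0).sum(axis=0)
            counts = (~in_bag).sum(axis=0)
            oob_pred = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        oob_mask = counts > 0
        classes = None
    else:
        classes = tuple(bagger.classes_)
        votes = np.zeros((n, len(classes)))
        for t, tree in enumerate(bagger.estimators_):
            proba = tree.predict_proba(X)
            votes[~in_bag[t]] += proba[~in_bag[t]]
        counts = (~in_bag).sum(axis=0)
        oob_mask = counts > 0
        winner = votes.argmax(axis=1)
        oob_pred = np.array([classes[w] for w in winner], dtype=object)
        oob_pred[~oob_mask] = None
    return ForestModel(
        task=task,
        target=target,
        predictors=tuple(predictors),
        n_trees=n_trees,
        mtry=mtry,
        ensemble=bagger,
        bootstrap_indices=boot,
        oob_prediction=oob_pred,
        oob_mask=oob_mask,
        classes=classes,
    )


def oob_metrics(model: ForestModel, data: Dataset) -> dict:
    """Out-of-bag performance of a fitted forest on its training data.

    Regression: OOB R² = 1 - SSE_oob / SST.  Classification: OOB
    misclassification rate plus the confusion table.  Rows that were
    never OOB (possible with very few trees) are excluded with a warning.
    """
    mask = model.oob_mask
    if not mask.all():
        warnings.warn(
            f"{int((~mask).sum())} rows were in-bag for every tree and are "
            "excluded from OOB metrics",
            stacklevel=2,
        )
    if not mask.any():
        raise ValueError("no rows have OOB predictions; increase n_trees")
    if model.task == "regression":
        y = data.to_numeric([model.target])[model.target].to_numpy()[mask]
        pred = model.oob_prediction[mask]
        sse = float(((y - pred) ** 2).sum())
        sst = float(((y - y.mean()) ** 2).sum())
        return {"task": "regression", "oob_r2": 1.0 - sse / sst if sst > 0 else 0.0,
                "n_oob": int(mask.sum())}
    y = data.df[model.target].astype(str).to_numpy()[mask]
    pred = np.array([str(v) for v in model.oob_prediction[mask]])
    err = float((y != pred).mean())
    confusion = pd.crosstab(
        pd.Series(y, name="observed"), pd.Series(pred, name="predicted")
    )
    return {
        "task": "classification",
        "oob_error": err,
        "confusion": confusion,
        "n_oob": int(mask.sum()),
    }
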