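"""Graphical causal inference on a fixed DAG.

Once a causal structure is fixed — learned from data or supplied from
field knowledge — this module answers the interventional questions:
which conditioning sets deconfound a treatment-outcome pair (backdoor
criterion via d-separation), what are the standardized path coefficients
of the linear structural model, what is the total effect along directed
paths, and what does the full intervention curve E[Y | do(x)] look like
when the outcome responds nonlinearly.

The average causal effect (ACE) is the derivative of E[Y | do(x)] with
respect to the intervened value; for a linear structural model it is a
single number (the backdoor-adjusted regression slope, equal to the sum
over directed paths of products of path coefficients), while for
nonlinear responses :func:`do_curve` traces ACE(x) along a grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor

from .dag import DAG
from .dataset import Dataset
from .exact import all_undirected_paths, path_is_blocked

__all__ = [
    "AdjustmentSet",
    "CausalEffect",
    "InterventionCurve",
    "d_separated",
    "backdoor_sets",
    "path_coefficients",
    "total_effect",
    "ace_adjusted",
    "do_curve",
]


# ---------------------------------------------------------------------------
# d-separation (reachability / Bayes-ball)


def d_separated(
    dag: DAG,
    xs: Iterable[str],
    ys: Iterable[str],
    given: Iterable[str] = (),
) -> bool:
    """True iff every path between ``xs`` and ``ys`` is blocked given ``given``.

    Implemented as the standard reachability ("Bayes-ball") procedure over
    (node, direction) states, linear in the number of edges per query:
    a chain or fork is blocked when its middle node is conditioned on, a
    collider is blocked unless it or one of its descendants is.
    """
    xs, ys, zs = set(xs), set(ys), set(given)
    for name, s in (("X", xs), ("Y", ys), ("Z", zs)):
        unknown = s - set(dag.nodes)
        if unknown:
            raise ValueError(f"{name} contains unknown nodes {sorted(unknown)}")
    if xs & ys or xs & zs or ys & zs:
        raise ValueError("X, Y and Z must be pairwise disjoint")

    # ancestors of Z (inclusive): a collider passes the ball iff it is in here
    anc_z: set[str] = set(zs)
    stack = list(zs)
    while stack:
        v = stack.pop()
        for p in dag.parents(v):
            if p not in anc_z:
                anc_z.add(p)
                stack.append(p)

    # phase 2 of Bayes-ball: traverse (node, came-from-child?) states
    visited: set[tuple[str, bool]] = set()
    agenda: list[tuple[str, bool]] = [(x, True) for x in xs]
    while agenda:
        node, up = agenda.pop()
        if (node, up) in visited:
            continue
        visited.add((node, up))
        if node not in zs and node in ys:
            return False
        if up:
            if node not in zs:
                agenda.extend((p, True) for p in dag.parents(node))
                agenda.extend((c, False) for c in dag.children(node))
        else:
            if node not in zs:
                agenda.extend((c, False) for c in dag.children(node))
            if node in anc_z:  # collider with conditioned descendant: bounce back
                agenda.extend((p, True) for p in dag.parents(node))
    return True


# ---------------------------------------------------------------------------
# backdoor adjustment


@dataclass(frozen=True)
class AdjustmentSet:
    """A conditioning set that deconfounds a treatment-outcome pair."""

    treatment: str
    outcome: str
    conditioning: frozenset[str]
    minimal: bool = False

    def __iter__(self):
        return iter(sorted(self.conditioning))


def _backdoor_valid(dag: DAG, treatment: str, outcome: str, zs: frozenset[str]) -> bool:
    if zs & (dag.descendants(treatment) | {treatment, outcome}):
        return False
    mutilated = dag.remove_outgoing(treatment)
    return d_separated(mutilated, {treatment}, {outcome}, zs)


def backdoor_sets(
    dag: DAG,
    treatment: str,
    outcome: str,
    minimal_only: bool = True,
    max_size: int | None = None,
) -> list[AdjustmentSet]:
    """All (or all minimal) valid backdoor adjustment sets.

    Candidates are subsets of the non-descendants of the treatment; a set
    is valid when it d-separates treatment from outcome in the graph with
    the treatment's outgoing edges removed.  Results are sorted by size
    then lexicographically, so the first entry is the canonical smallest
    set.  Subset enumeration is exponential in the candidate pool; cap it
    with ``max_size`` on large graphs.
    """
    if treatment == outcome:
        raise ValueError("treatment and outcome must differ")
    for v in (treatment, outcome):
        if v not in dag.nodes:
            raise ValueError(f"node {v!r} not in DAG")
    forbidden = dag.descendants(treatment) | {treatment, outcome}
    pool = sorted(set(dag.nodes) - forbidden)
    limit = len(pool) if max_size is None else min(max_size, len(pool))
    valid: list[frozenset[str]] = []
    for size in range(limit + 1):
        for zs in combinations(pool, size):
            z = frozenset(zs)
            if minimal_only and any(v < z for v in valid):
                continue
            if _backdoor_valid(dag, treatment, outcome, z):
                valid.append(z)
    valid.sort(key=lambda z: (len(z), tuple(sorted(z))))
    out = []
    for z in valid:
        is_minimal = not any(v < z for v in valid)
        out.append(AdjustmentSet(treatment, outcome, z, minimal=is_minimal))
    return out


# ---------------------------------------------------------------------------
# linear effects


@dataclass(frozen=True)
class CausalEffect:
    """A direct or total causal effect estimate with its uncertainty."""

    treatment: str
    outcome: str
    kind: str  # "direct" | "total"
    estimate: float
    se: float
    method: str  # "path-ols" | "adjusted-ols" | "dml"
    adjustment: frozenset[str] = frozenset()
    units: str = "standardized"

    def __post_init__(self):
        if self.se < 0:
            raise ValueError("se must be nonnegative")


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS with intercept; returns (coef without intercept, se without intercept)."""
    n = len(y)
    X1 = np.column_stack([np.ones(n), X])
    p = X1.shape[1]
    gram = X1.T @ X1
    try:
        gram_inv = np.linalg.inv(gram)
    except np.linalg.LinAlgError:
        warnings.warn("collinear regressors; using pseudo-inverse", stacklevel=3)
        gram_inv = np.linalg.pinv(gram)
    beta = gram_inv @ (X1.T @ y)
    resid = y - X1 @ beta
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.clip(np.diag(gram_inv) * sigma2, 0.0, None))
    return beta[1:], se[1:]


def _numeric_standardized(data: Dataset, columns: Sequence[str]) -> pd.DataFrame:
    num = data.to_numeric(columns)
    sd = num.std(ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance columns {zero} cannot be standardized")
    return (num - num.mean()) / sd


def path_coefficients(
    data: Dataset, dag: DAG, standardize: bool = True
) -> dict[tuple[str, str], tuple[float, float]]:
    """Standardized edge weights of the linear structural model.

    For each node with parents, the OLS regression of the node on all its
    parents yields the path coefficient of every incoming edge (direct
    effects in the linear model).  Binary/ordinal columns enter as numeric
    codes.  Returns edge -> (estimate, se).
    """
    cols = [c for c in dag.nodes if c in data.columns]
    num = _numeric_standardized(data, cols) if standardize else data.to_numeric(cols)
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for node in dag.nodes:
        parents = [p for p in dag.parents(node)]
        if not parents:
            continue
        coef, se = _ols(num[node].to_numpy(), num[parents].to_numpy())
        for p, b, s in zip(parents, coef, se):
            out[(p, node)] = (float(b), float(s))
    return out


def total_effect(
    dag: DAG,
    path_coeffs: Mapping[tuple[str, str], tuple[float, float]],
    treatment: str,
    outcome: str,
) -> CausalEffect:
    """Total effect as the sum over directed paths of edge-weight products.

    The standard error follows by the delta method: the gradient of the
    path-sum with respect to each edge weight is the sum of the products
    of the other edges on paths through it; edge estimates from different
    child regressions are treated as independent (they use disjoint
    response variables), and within one child's regression the OLS
    covariance is approximated as diagonal.
    """
    paths = dag.directed_paths(treatment, outcome)
    est = 0.0
    grad: dict[tuple[str, str], float] = {}
    for path in paths:
        edges = list(zip(path, path[1:]))
        prod = 1.0
        for e in edges:
            prod *= path_coeffs[e][0]
        est += prod
        for e in edges:
            others = 1.0
            for f in edges:
                if f != e:
                    others *= path_coeffs[f][0]
            grad[e] = grad.get(e, 0.0) + others
    var = sum(g * g * path_coeffs[e][1] ** 2 for e, g in grad.items())
    return CausalEffect(
        treatment=treatment,
        outcome=outcome,
        kind="total",
        estimate=float(est),
        se=float(np.sqrt(var)),
        method="path-ols",
    )


def ace_adjusted(
    data: Dataset,
    dag: DAG,
    treatment: str,
    outcome: str,
    adjustment: AdjustmentSet | Iterable[str] | None = None,
    standardize: bool = True,
) -> CausalEffect:
    """Backdoor-adjusted ACE: OLS slope of outcome on treatment + Z.

    ``adjustment`` defaults to the smallest minimal backdoor set
    (lexicographic tie-break).  An invalid set is refused with the open
    backdoor path named.  Under a linear structural model this slope is
    the total causal effect.
    """
    if adjustment is None:
        sets = backdoor_sets(dag, treatment, outcome, minimal_only=True)
        if not sets:
            raise ValueError(
                f"no valid backdoor adjustment set for {treatment} -> {outcome}"
            )
        zs = sets[0].conditioning
    elif isinstance(adjustment, AdjustmentSet):
        zs = adjustment.conditioning
    else:
        zs = frozenset(adjustment)
    if not _backdoor_valid(dag, treatment, outcome, zs):
        mutilated = dag.remove_outgoing(treatment)
        open_path = None
        for path in all_undirected_paths(mutilated, treatment, outcome):
            if not path_is_blocked(mutilated, path, zs):
                open_path = path
                break
        raise ValueError(
            f"invalid adjustment set {sorted(zs)} for {treatment} -> {outcome}: "
            f"open backdoor path {' - '.join(open_path) if open_path else '(descendant of treatment in Z)'}"
        )
    cols = [treatment, *sorted(zs)]
    num = (
        _numeric_standardized(data, cols + [outcome])
        if standardize
        else data.to_numeric(cols + [outcome])
    )
    coef, se = _ols(num[outcome].to_numpy(), num[cols].to_numpy())
    return CausalEffect(
        treatment=treatment,
        outcome=outcome,
        kind="total",
        estimate=float(coef[0]),
        se=float(se[0]),
        method="adjusted-ols",
        adjustment=zs,
        units="standardized" if standardize else "natural",
    )


# ---------------------------------------------------------------------------
# do(x) intervention curves


@dataclass(frozen=True)
class InterventionCurve:
    """E[Y | do(x)] on a grid, with a central band and the pointwise ACE(x)."""

    treatment: str
    outcome: str
    grid: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    ace: np.ndarray
    extrapolated: np.ndarray  # bool mask: grid point outside observed support

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.grid,
                "mean": self.mean,
                "lower": self.lower,
                "upper": self.upper,
                "ace": self.ace,
                "extrapolated": self.extrapolated,
            }
        )


def _central_differences(grid: np.ndarray, values: np.ndarray) -> np.ndarray:
    out = np.empty_like(values)
    out[1:-1] = (values[2:] - values[:-2]) / (grid[2:] - grid[:-2])
    out[0] = (values[1] - values[0]) / (grid[1] - grid[0])
    out[-1] = (values[-1] - values[-2]) / (grid[-1] - grid[-2])
    return out


def do_curve(
    data: Dataset,
    dag: DAG,
    treatment: str,
    outcome: str,
    grid: Sequence[float] | None = None,
    adjustment: AdjustmentSet | Iterable[str] | None = None,
    n_members: int = 20,
    hidden: int = 32,
    band: float = 0.90,
    seed: int = 0,
) -> InterventionCurve:
    """Nonparametric intervention curve via a bootstrap ensemble.

    Fits ``n_members`` small neural regressors of the outcome on
    (treatment, Z) to bootstrap resamples, then applies the backdoor
    formula: E[Y | do(x)] is the prediction at treatment = x averaged over
    the empirical distribution of the adjustment covariates Z.  The band
    is the central ``band`` mass of the ensemble of curve means — an
    ensemble realization of predictive uncertainty — and ACE(x) is the
    central-difference derivative of the mean curve.
    """
    if adjustment is None:
        sets = backdoor_sets(dag, treatment, outcome, minimal_only=True)
        if not sets:
            raise ValueError(
                f"no valid backdoor adjustment set for {treatment} -> {outcome}"
            )
        zs = sorted(sets[0].conditioning)
    elif isinstance(adjustment, AdjustmentSet):
        zs = sorted(adjustment.conditioning)
    else:
        zs = sorted(adjustment)

    num = data.to_numeric([treatment, *zs, outcome])
    t = num[treatment].to_numpy()
    if grid is None:
        grid_arr = np.linspace(np.quantile(t, 0.05), np.quantile(t, 0.95), 11)
    else:
        grid_arr = np.asarray(list(grid), dtype=float)
    if len(grid_arr) < 2 or np.any(np.diff(grid_arr) <= 0):
        raise ValueError("grid must be strictly increasing with >= 2 points")
    extrapolated = (grid_arr < t.min()) | (grid_arr > t.max())
    if extrapolated.any():
        warnings.warn(
            f"{int(extrapolated.sum())} grid points outside the observed "
            f"support of {treatment}; flagged as extrapolation",
            stacklevel=2,
        )

    X = num[[treatment, *zs]].to_numpy()
    y = num[outcome].to_numpy()
    n = len(y)
    if n == 0:
        raise ValueError("no rows available to fit the intervention curve")
    # standardize inputs for the network, keep outputs in natural units
    x_mean, x_sd = X.mean(axis=0), X.std(axis=0)
    x_sd[x_sd == 0] = 1.0
    Z = num[zs].to_numpy() if zs else np.empty((n, 0))

    rng = np.random.default_rng(seed)
    member_curves = np.empty((n_members, len(grid_arr)))
    for m in range(n_members):
        idx = rng.integers(0, n, size=n)
        net = MLPRegressor(
            hidden_layer_sizes=(hidden,),
            early_stopping=True,
            n_iter_no_change=10,
            max_iter=400,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        net.fit((X[idx] - x_mean) / x_sd, y[idx])
        for j, x0 in enumerate(grid_arr):
            Xq = np.column_stack([np.full(n, x0), Z]) if zs else np.full((n, 1), x0)
            member_curves[m, j] = float(net.predict((Xq - x_mean) / x_sd).mean())

    mean = member_curves.mean(axis=0)
    alpha = (1.0 - band) / 2.0
    lower = np.quantile(member_curves, alpha, axis=0)
    upper = np.quantile(member_curves, 1.0 - alpha, axis=0)
    ace = _central_differences(grid_arr, mean)
    return InterventionCurve(
        treatment=treatment,
        outcome=outcome,
        grid=grid_arr,
        mean=mean,
        lower=np.minimum(lower, mean),
        upper=np.maximum(upper, mean),
        ace=ace,
        extrapolated=extrapolated,
    )
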