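"""Structural causal model (SCM) simulation.

An SCM couples a DAG with a functional mechanism and a noise scale per
node.  Sampling proceeds ancestrally, in topological order: each node is
its mechanism applied to the already-sampled *observed* parent values plus
Gaussian noise, then mapped to its declared measurement scale (binary
nodes threshold the latent value, ordinal nodes bin it at fixed cut
points).  Because every mechanism reads observed parent values, the
sampled table is exactly Markov with respect to the generating DAG — the
property that makes these datasets usable as ground truth for structure
learning and effect estimation.

Three presets (:func:`food_template`) emulate the structure of typical
food-quality studies: a wide, highly collinear wheat baking table, a small
mixed-scale dairy consumer table, and a wine physicochemistry table with a
10-level tasting grade.  Template coefficients are fixed, documented
constants chosen to mimic qualitative correlation patterns — they are
presets, not estimates of any real dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dag import DAG, CycleError
from .dataset import BINARY, CONTINUOUS, ORDINAL, ColumnKind, Dataset, binary, continuous, ordinal

__all__ = [
    "Transform",
    "Mechanism",
    "SCMSpec",
    "make_scm",
    "sample_dataset",
    "discretize_ordinal",
    "implied_covariance",
    "food_template",
]


# ---------------------------------------------------------------------------
# mechanisms


@dataclass(frozen=True)
class Transform:
    """Per-parent input transform g(x) inside a mechanism.

    tags: ``identity`` g(x)=x; ``saturating`` g(x)=softplus((x-center)/scale),
    a smooth ramp that is ~0 below the change point and ~linear above it;
    ``quadratic`` g(x)=(x-center)**2.
    """

    tag: str = "identity"
    center: float = 0.0
    scale: float = 1.0

    def __post_init__(self):
        if self.tag not in ("identity", "saturating", "quadratic"):
            raise ValueError(f"unknown transform tag {self.tag!r}")
        if self.scale <= 0:
            raise ValueError("transform scale must be positive")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.tag == "identity":
            return x
        if self.tag == "saturating":
            z = (x - self.center) / self.scale
            # numerically stable softplus
            return np.logaddexp(0.0, z)
        return (x - self.center) ** 2


IDENTITY = Transform()


@dataclass(frozen=True)
class Mechanism:
    """Node mechanism: intercept + sum of coefficient * g(parent)."""

    intercept: float = 0.0
    coeffs: tuple[tuple[str, float], ...] = ()
    transforms: tuple[tuple[str, Transform], ...] = ()

    def coeff_map(self) -> dict[str, float]:
        return dict(self.coeffs)

    def transform_for(self, parent: str) -> Transform:
        return dict(self.transforms).get(parent, IDENTITY)

    def is_linear(self) -> bool:
        return all(t.tag == "identity" for _, t in self.transforms)

    def evaluate(self, parent_values: Mapping[str, np.ndarray], n: int) -> np.ndarray:
        out = np.full(n, self.intercept, dtype=float)
        for parent, coef in self.coeffs:
            out += coef * self.transform_for(parent)(parent_values[parent])
        return out


# ---------------------------------------------------------------------------
# node kinds (with generation parameters)


@dataclass(frozen=True)
class NodeKind:
    """Measurement scale of a node plus its latent-to-observed map.

    continuous: observed = latent.
    binary: observed = 1[latent > threshold] (probit-style latent Gaussian).
    ordinal: observed = label of the bin of latent under cut_points.
    """

    kind: str = CONTINUOUS
    threshold: float = 0.0
    cut_points: tuple[float, ...] = ()
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in (CONTINUOUS, BINARY, ORDINAL):
            raise ValueError(f"unknown node kind {self.kind!r}")
        if self.kind == ORDINAL:
            if len(self.labels) != len(self.cut_points) + 1:
                raise ValueError("need len(labels) == len(cut_points) + 1")
            if any(
                a >= b for a, b in zip(self.cut_points, self.cut_points[1:])
            ):
                raise ValueError("ordinal cut points must be strictly increasing")

    def to_column_kind(self) -> ColumnKind:
        if self.kind == ORDINAL:
            return ordinal(self.labels)
        return ColumnKind(self.kind)


def discretize_ordinal(
    values: np.ndarray | Sequence[float],
    cut_points: Sequence[float],
    labels: Sequence[Any],
) -> np.ndarray:
    """Monotone binning of a continuous vector into ordered labels.

    ``cut_points`` are the K-1 strictly increasing bin boundaries for K
    labels; values <= the first cut map to the first label.
    """
    cut_points = list(cut_points)
    if len(labels) != len(cut_points) + 1:
        raise ValueError("need len(labels) == len(cut_points) + 1")
    if any(a >= b for a, b in zip(cut_points, cut_points[1:])):
        raise ValueError("cut points must be strictly increasing")
    idx = np.searchsorted(np.asarray(cut_points, dtype=float), np.asarray(values, dtype=float))
    return np.asarray([str(labels[i]) for i in idx])


# ---------------------------------------------------------------------------
# SCMSpec


@dataclass(frozen=True)
class SCMSpec:
    """A validated structural causal model: DAG + mechanisms + noise + kinds.

    ``latent`` nodes are sampled like any other but dropped from the output
    table; they serve as shared factors inducing correlation among observed
    variables.
    """

    dag: DAG
    mechanisms: tuple[tuple[str, Mechanism], ...]
    noise_sd: tuple[tuple[str, float], ...]
    kinds: tuple[tuple[str, NodeKind], ...]
    latent: frozenset[str] = frozenset()
    name: str = "scm"

    def __post_init__(self):
        mechs = dict(self.mechanisms)
        sds = dict(self.noise_sd)
        kinds = dict(self.kinds)
        nodes = set(self.dag.nodes)
        for d, label in ((mechs, "mechanism"), (sds, "noise_sd"), (kinds, "kind")):
            if set(d) != nodes:
                raise ValueError(f"{label} must be specified for every node")
        for node, mech in mechs.items():
            declared_parents = set(self.dag.parents(node))
            used = {p for p, _ in mech.coeffs}
            if used != declared_parents:
                raise ValueError(
                    f"mechanism of {node!r} uses parents {sorted(used)} but DAG "
                    f"declares {sorted(declared_parents)}"
                )
        for node, sd in sds.items():
            if not sd > 0:
                raise ValueError(f"noise_sd of {node!r} must be positive")
        if not self.latent <= nodes:
            raise ValueError("latent names must be declared nodes")

    # convenience dict views
    def mechanism_of(self, node: str) -> Mechanism:
        return dict(self.mechanisms)[node]

    def noise_of(self, node: str) -> float:
        return dict(self.noise_sd)[node]

    def kind_of(self, node: str) -> NodeKind:
        return dict(self.kinds)[node]

    def observed_nodes(self) -> tuple[str, ...]:
        return tuple(v for v in self.dag.nodes if v not in self.latent)

    def observed_dag(self) -> DAG:
        """DAG restricted to observed nodes (edges among observed only)."""
        obs = set(self.observed_nodes())
        return DAG(
            self.observed_nodes(),
            [(a, b) for a, b in self.dag.edges if a in obs and b in obs],
        )

    def is_linear_gaussian(self) -> bool:
        return all(
            m.is_linear() and self.kind_of(v).kind == CONTINUOUS
            for v, m in self.mechanisms
        )

    # -- JSON serialization ---------------------------------------------

    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "nodes": list(self.dag.nodes),
            "edges": [list(e) for e in self.dag.edges],
            "latent": sorted(self.latent),
            "mechanisms": {
                node: {
                    "intercept": m.intercept,
                    "coeffs": {p: c for p, c in m.coeffs},
                    "transforms": {
                        p: {"tag": t.tag, "center": t.center, "scale": t.scale}
                        for p, t in m.transforms
                    },
                }
                for node, m in self.mechanisms
            },
            "noise_sd": {node: sd for node, sd in self.noise_sd},
            "kinds": {
                node: {
                    "kind": k.kind,
                    "threshold": k.threshold,
                    "cut_points": list(k.cut_points),
                    "labels": list(k.labels),
                }
                for node, k in self.kinds
            },
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SCMSpec":
        payload = json.loads(text)
        dag = DAG(payload["nodes"], [tuple(e) for e in payload["edges"]])
        mechanisms = tuple(
            (
                node,
                Mechanism(
                    intercept=m["intercept"],
                    coeffs=tuple(sorted(m["coeffs"].items())),
                    transforms=tuple(
                        (p, Transform(t["tag"], t["center"], t["scale"]))
                        for p, t in sorted(m["transforms"].items())
                    ),
                ),
            )
            for node, m in payload["mechanisms"].items()
        )
        kinds = tuple(
            (
                node,
                NodeKind(
                    k["kind"],
                    k.get("threshold", 0.0),
                    tuple(k.get("cut_points", ())),
                    tuple(k.get("labels", ())),
                ),
            )
            for node, k in payload["kinds"].items()
        )
        return cls(
            dag=dag,
            mechanisms=mechanisms,
            noise_sd=tuple(payload["noise_sd"].items()),
            kinds=kinds,
            latent=frozenset(payload.get("latent", ())),
            name=payload.get("name", "scm"),
        )

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def make_scm(
    dag: DAG,
    coefficients: Mapping[tuple[str, str], float],
    noise_sd: Mapping[str, float] | float = 1.0,
    kinds: Mapping[str, NodeKind] | None = None,
    intercepts: Mapping[str, float] | None = None,
    transforms: Mapping[tuple[str, str], Transform] | None = None,
    latent: Iterable[str] = (),
    name: str = "scm",
) -> SCMSpec:
    """Assemble and validate an :class:`SCMSpec`.

    ``coefficients`` maps each DAG edge ``(parent, child)`` to its linear
    weight; a coefficient for a pair that is not an edge is an error, and
    every edge must receive one.  ``transforms`` optionally attaches a
    nonlinearity to an edge (applied to the parent value before the
    coefficient).
    """
    edge_set = set(dag.edges)
    for pair in coefficients:
        if tuple(pair) not in edge_set:
            raise ValueError(f"coefficient supplied for non-edge {pair}")
    missing = edge_set - {tuple(p) for p in coefficients}
    if missing:
        raise ValueError(f"edges without coefficients: {sorted(missing)}")
    if transforms:
        for pair in transforms:
            if tuple(pair) not in edge_set:
                raise ValueError(f"transform supplied for non-edge {pair}")
    kinds = dict(kinds or {})
    intercepts = dict(intercepts or {})
    transforms = dict(transforms or {})
    if not isinstance(noise_sd, Mapping):
        noise_sd = {v: float(noise_sd) for v in dag.nodes}

    mechanisms = []
    for node in dag.nodes:
        coeffs = tuple(
            sorted((p, float(coefficients[(p, node)])) for p in dag.parents(node))
        )
        trans = tuple(
            sorted(
                (p, transforms[(p, node)])
                for p in dag.parents(node)
                if (p, node) in transforms
            )
        )
        mechanisms.append(
            (node, Mechanism(float(intercepts.get(node, 0.0)), coeffs, trans))
        )
    return SCMSpec(
        dag=dag,
        mechanisms=tuple(mechanisms),
        noise_sd=tuple((v, float(noise_sd[v])) for v in dag.nodes),
        kinds=tuple((v, kinds.get(v, NodeKind())) for v in dag.nodes),
        latent=frozenset(latent),
        name=name,
    )


# ---------------------------------------------------------------------------
# sampling


def sample_dataset(scm: SCMSpec, n: int, seed: int) -> Dataset:
    """Draw ``n`` ancestral samples from the SCM.

    One global integer seed is split deterministically per node (keyed by
    the node's position in sorted name order), so the same (scm, n, seed)
    always reproduces the same table bit-exactly, and adding an unrelated
    node does not perturb the draws of existing ones.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    order = scm.dag.topological_order()
    sorted_nodes = sorted(scm.dag.nodes)
    streams = {
        node: np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        for i, node in enumerate(sorted_nodes)
    }
    values: dict[str, np.ndarray] = {}
    observed: dict[str, np.ndarray] = {}
    for node in order:
        mech = scm.mechanism_of(node)
        latent_value = mech.evaluate(values, n) + streams[node].normal(
            0.0, scm.noise_of(node), size=n
        )
        kind = scm.kind_of(node)
        if kind.kind == CONTINUOUS:
            obs: np.ndarray = latent_value
        elif kind.kind == BINARY:
            obs = (latent_value > kind.threshold).astype(int)
        else:
            obs = discretize_ordinal(latent_value, kind.cut_points, kind.labels)
        # children read the observed value, keeping the table Markov w.r.t. the DAG
        if kind.kind == ORDINAL:
            codes = pd.Categorical(obs, categories=kind.labels, ordered=True).codes
            values[node] = np.asarray(codes, dtype=float)
        else:
            values[node] = np.asarray(obs, dtype=float)
        observed[node] = obs

    cols = scm.observed_nodes()
    df = pd.DataFrame({c: observed[c] for c in cols})
    kinds = {c: scm.kind_of(c).to_column_kind() for c in cols}
    return Dataset(df, kinds, provenance={"seed": seed, "scm": scm.name, "n": n})


def implied_covariance(scm: SCMSpec, nodes: Sequence[str] | None = None) -> pd.DataFrame:
    """Closed-form covariance of a linear-Gaussian SCM.

    With coefficient matrix B (B[i, j] = weight of edge i -> j) and noise
    variances D, the implied covariance is (I - B)^-T D (I - B)^-1.  Only
    valid when all mechanisms are linear and all nodes continuous.
    """
    if not scm.is_linear_gaussian():
        raise ValueError("implied covariance requires a linear-Gaussian SCM")
    all_nodes = list(scm.dag.nodes)
    idx = {v: i for i, v in enumerate(all_nodes)}
    p = len(all_nodes)
    B = np.zeros((p, p))
    for child in all_nodes:
        for parent, coef in scm.mechanism_of(child).coeffs:
            B[idx[parent], idx[child]] = coef
    D = np.diag([scm.noise_of(v) ** 2 for v in all_nodes])
    inv = np.linalg.inv(np.eye(p) - B)
    sigma = inv.T @ D @ inv
    frame = pd.DataFrame(sigma, index=all_nodes, columns=all_nodes)
    keep = list(nodes) if nodes is not None else list(scm.observed_nodes())
    return frame.loc[keep, keep]


# ---------------------------------------------------------------------------
# templates


def _dairy_template() -> SCMSpec:
    # Preset mimicking a consumer study of fermented milk products:
    # pre-treatment temperature (deg C) and fat content are exogenous;
    # taste and quality grade are colliders.  Edge weights are fixed
    # constants chosen so the grade-temperature correlation is moderate
    # and negative (~ -0.45) and the taste-fat correlation positive.
    nodes = ["temperature", "fat", "pH", "colour", "odour", "turbidity", "taste", "grade"]
    edges = [
        ("temperature", "pH"),
        ("temperature", "colour"),
        ("temperature", "odour"),
        ("temperature", "turbidity"),
        ("temperature", "taste"),
        ("temperature", "grade"),
        ("fat", "taste"),
        ("fat", "grade"),
        ("turbidity", "grade"),
        ("odour", "grade"),
        ("colour", "taste"),
    ]
    dag = DAG(nodes, edges)
    coefficients = {
        ("temperature", "pH"): -0.05,
        ("temperature", "colour"): -0.03,
        ("temperature", "odour"): 0.04,
        ("temperature", "turbidity"): 0.05,
        ("temperature", "taste"): -0.03,
        ("temperature", "grade"): -0.024,
        ("fat", "taste"): 0.55,
        ("fat", "grade"): 0.40,
        ("turbidity", "grade"): -0.50,
        ("odour", "grade"): -0.45,
        ("colour", "taste"): 0.60,
    }
    intercepts = {
        "temperature": 47.0,
        "fat": 3.0,
        "pH": 6.63 + 0.05 * 47.0,      # keeps mean pH at 6.63
        "colour": 50.0 + 0.03 * 47.0,  # keeps mean colour at 50
        "odour": -0.04 * 47.0,
        "turbidity": -0.05 * 47.0,
        "taste": 0.03 * 47.0 - 0.55 * 3.0 - 0.60 * 50.0,
        "grade": 0.024 * 47.0 - 0.40 * 3.0 + 0.50 * 0.5 + 0.45 * 0.5,
    }
    noise = {
        "temperature": 13.0,
        "fat": 1.0,
        "pH": 0.50,
        "colour": 0.30,
        "odour": 0.70,
        "turbidity": 0.80,
        "taste": 1.00,
        "grade": 0.80,
    }
    kinds = {
        "odour": NodeKind(BINARY, threshold=0.0),
        "turbidity": NodeKind(BINARY, threshold=0.0),
        "taste": NodeKind(BINARY, threshold=0.0),
        "grade": NodeKind(
            ORDINAL, cut_points=(-0.55, 0.55), labels=("low", "medium", "high")
        ),
    }
    return make_scm(
        dag, coefficients, noise, kinds=kinds, intercepts=intercepts, name="dairy"
    )


_WHEAT_ACTIVE = (
    "protein",
    "wet_gluten",
    "falling_number",
    "water_absorption",
    "dough_resistance",
    "resistance_extensibility",
    "total_glutenin",
    "thmm_glutenin",
    "alpha_gliadin",
    "softening_degree",
)

# standardized direct path weights into bread loaf volume; protein dominates,
# softening degree is detrimental.  thmm_glutenin acts only through protein.
_WHEAT_DIRECT = {
    "protein": 0.71,
    "wet_gluten": 0.25,
    "falling_number": 0.20,
    "water_absorption": 0.22,
    "dough_resistance": 0.18,
    "resistance_extensibility": -0.15,
    "total_glutenin": 0.30,
    "alpha_gliadin": 0.16,
    "softening_degree": -0.24,
}


def _wheat_template(seed: int) -> SCMSpec:
    # 45 continuous predictors of a continuous baking-quality volume:
    # 10 actives (9 direct parents of volume plus thmm_glutenin, an
    # indirect cause through protein) and 35 distractors tied to the
    # actives through 4 shared latent factors.
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(97,)))
    factors = [f"_factor{i}" for i in range(1, 5)]
    distractors = [f"d{i:02d}" for i in range(1, 36)]
    nodes = factors + list(_WHEAT_ACTIVE) + distractors + ["volume"]

    edges: list[tuple[str, str]] = []
    coefficients: dict[tuple[str, str], float] = {}
    noise: dict[str, float] = {f: 1.0 for f in factors}

    # actives load on two factors each; moderate unique noise
    for i, name in enumerate(_WHEAT_ACTIVE):
        f1, f2 = factors[i % 4], factors[(i + 1) % 4]
        edges += [(f1, name), (f2, name)]
        coefficients[(f1, name)] = 0.70
        coefficients[(f2, name)] = 0.45
        noise[name] = 0.55
    # thmm -> protein: indirect cause of volume
    edges.append(("thmm_glutenin", "protein"))
    coefficients[("thmm_glutenin", "protein")] = 0.42

    # distractors: pure factor children, random signed loadings
    for name in distractors:
        f1, f2 = rng.choice(factors, size=2, replace=False)
        l1 = rng.uniform(0.55, 0.85) * rng.choice([-1.0, 1.0])
        l2 = rng.uniform(0.25, 0.55) * rng.choice([-1.0, 1.0])
        edges += [(str(f1), name), (str(f2), name)]
        coefficients[(str(f1), name)] = float(l1)
        coefficients[(str(f2), name)] = float(l2)
        noise[name] = float(rng.uniform(0.4, 0.8))

    for name, coef in _WHEAT_DIRECT.items():
        edges.append((name, "volume"))
        coefficients[(name, "volume")] = coef
    noise["volume"] = 0.22  # small: actives explain most of the volume variance

    dag = DAG(nodes, edges)
    return make_scm(dag, coefficients, noise, latent=factors, name="wheat")


def _wine_template() -> SCMSpec:
    # 10 physicochemical predictors plus a 10-level ordinal tasting grade.
    # Quality parents are exogenous and mutually non-adjacent; the other
    # predictors are their children, so no predictor reaches quality
    # through another predictor (total effects are direct or zero).
    parents_of_quality = {
        "alcohol": 0.35,
        "volatile_acidity": -0.20,
        "sulphates": 0.18,
        "free_sulfur_dioxide": 0.12,
        "chlorides": -0.08,
    }
    others = {
        "total_sulfur_dioxide": {"free_sulfur_dioxide": 0.85},
        "residual_sugar": {"alcohol": -0.45},
        "citric_acid": {"fixed_acidity": 0.60, "volatile_acidity": -0.40},
        "pH": {"fixed_acidity": -0.65, "volatile_acidity": 0.20},
    }
    roots = sorted(set(parents_of_quality) | {"fixed_acidity"})
    nodes = roots + sorted(others) + ["quality"]
    edges: list[tuple[str, str]] = []
    coefficients: dict[tuple[str, str], float] = {}
    noise: dict[str, float] = {r: 1.0 for r in roots}
    for child, pmap in others.items():
        explained = sum(c * c for c in pmap.values())
        noise[child] = float(np.sqrt(max(1.0 - explained, 0.15)))
        for parent, coef in pmap.items():
            edges.append((parent, child))
            coefficients[(parent, child)] = coef
    for parent, coef in parents_of_quality.items():
        edges.append((parent, "quality"))
        coefficients[(parent, "quality")] = coef
    explained = sum(c * c for c in parents_of_quality.values())
    noise["quality"] = float(np.sqrt(1.0 - explained))  # unit-variance latent grade

    kinds = {
        "quality": NodeKind(
            ORDINAL,
            cut_points=tuple(np.linspace(-2.0, 2.0, 9)),
            labels=tuple(str(i) for i in range(1, 11)),
        )
    }
    dag = DAG(nodes, edges)
    return make_scm(dag, coefficients, noise, kinds=kinds, name="wine")


def food_template(name: str, seed: int = 0) -> SCMSpec:
    """Preset SCM emulating one of the three study designs.

    ``wheat``: 45 correlated continuous predictors, 10 with paths into a
    continuous quality (loaf volume) node; ``seed`` fixes the distractor
    loadings.  ``dairy``: 7 mixed-scale variables with exogenous
    temperature and fat and collider taste/grade.  ``wine``: 10 continuous
    predictors with a 10-level ordinal quality grade (positive alcohol
    path, negative volatile-acidity path).
    """
    if name == "dairy":
        return _dairy_template()
    if name == "wheat":
        return _wheat_template(seed)
    if name == "wine":
        return _wine_template()
    raise ValueError(f"unknown template {name!r}; expected wheat, dairy or wine")
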