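"""Exact reference algorithms for small graphs.

Brute-force counterparts of the scalable algorithms elsewhere in the
package: path-enumeration d-separation, exhaustive DAG enumeration, and
the exact score-weighted edge posterior.  They are exponential in the
number of nodes and intended for graphs of at most ~8 nodes, where they
serve as independent ground truth when validating the fast
implementations.
"""

from __future__ import annotations

from itertools import combinations, permutations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .dag import DAG


def all_undirected_paths(dag: DAG, source: str, target: str) -> list[tuple[str, ...]]:
    """All simple paths between source and target ignoring edge direction."""
    g = nx.Graph()
    g.add_nodes_from(dag.nodes)
    g.add_edges_from(dag.edges)
    return [tuple(p) for p in nx.all_simple_paths(g, source, target)]


def path_is_blocked(dag: DAG, path: Sequence[str], given: frozenset[str] | set[str]) -> bool:
    """Apply the chain/fork/collider blocking rules to one undirected path.

    A middle node m on the path is a collider when both path edges point
    into it; a collider blocks unless m or one of its descendants is
    conditioned on, while a chain or fork blocks exactly when m is
    conditioned on.
    """
    given = set(given)
    for i in range(1, len(path) - 1):
        prev, mid, nxt = path[i - 1], path[i], path[i + 1]
        is_collider = dag.has_edge(prev, mid) and dag.has_edge(nxt, mid)
        if is_collider:
            opened = mid in given or bool(dag.descendants(mid) & given)
            if not opened:
                return True
        else:
            if mid in given:
                return True
    return False


def d_separated_bruteforce(
    dag: DAG,
    xs: Iterable[str],
    ys: Iterable[str],
    given: Iterable[str] = (),
) -> bool:
    """d-separation by enumerating every undirected path (exponential)."""
    xs, ys, given = set(xs), set(ys), frozenset(given)
    for x in xs:
        for y in ys:
            for path in all_undirected_paths(dag, x, y):
                if not path_is_blocked(dag, path, given):
                    return False
    return True


def all_dags(nodes: Sequence[str]) -> list[DAG]:
    """Every labelled DAG on the given nodes (feasible for <= 4 nodes).

    Enumerates all orientations of all subsets of node pairs and keeps the
    acyclic ones; there are 25 DAGs on 3 labelled nodes and 543 on 4.
    """
    nodes = list(nodes)
    pairs = list(combinations(nodes, 2))
    out: list[DAG] = []
    # each unordered pair is absent, forward, or backward: 3^|pairs| graphs
    for code in range(3 ** len(pairs)):
        edges = []
        c = code
        for a, b in pairs:
            state, c = c % 3, c // 3
            if state == 1:
                edges.append((a, b))
            elif state == 2:
                edges.append((b, a))
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        if nx.is_directed_acyclic_graph(g):
            out.append(DAG(nodes, edges))
    return out


def exact_edge_posterior(
    dags: Sequence[DAG], log_scores: Sequence[float]
) -> dict[tuple[str, str], float]:
    """Edge marginals of the score-weighted posterior over an explicit DAG list.

    ``log_scores`` are per-DAG log posterior surrogates (e.g. total BIC);
    weights are softmax-normalized.
    """
    log_scores = np.asarray(log_scores, dtype=float)
    w = np.exp(log_scores - log_scores.max())
    w /= w.sum()
    post: dict[tuple[str, str], float] = {}
    for dag, weight in zip(dags, w):
        for e in dag.edges:
            post[e] = post.get(e, 0.0) + float(weight)
    return post


def minimal_backdoor_sets_bruteforce(
    dag: DAG, treatment: str, outcome: str
) -> list[frozenset[str]]:
    """All minimal valid backdoor sets by exhaustive subset enumeration.

    Candidates are non-descendants of the treatment; validity is checked
    with brute-force d-separation on the graph with the treatment's
    outgoing edges removed.
    """
    mutilated = dag.remove_outgoing(treatment)
    forbidden = dag.descendants(treatment) | {treatment, outcome}
    pool = sorted(set(dag.nodes) - forbidden)
    valid: list[frozenset[str]] = []
    for size in range(len(pool) + 1):
        for zs in combinations(pool, size):
            z = frozenset(zs)
            if any(v < z for v in valid):
                continue  # a strict subset is already valid: not minimal
            if d_separated_bruteforce(mutilated, {treatment}, {outcome}, z):
                valid.append(z)
    return sorted(valid, key=lambda z: (len(z), tuple(sorted(z))))


def random_dag(nodes: Sequence[str], edge_prob: float, rng: np.random.Generator) -> DAG:
    """A random DAG: random topological order, independent edge coin flips."""
    nodes = list(nodes)
    order = list(rng.permutation(nodes))
    edges = [
        (a, b)
        for i, a in enumerate(order)
        for b in order[i + 1 :]
        if rng.random() < edge_prob
    ]
    return DAG(nodes, edges)
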