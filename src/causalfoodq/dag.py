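"""Directed acyclic graphs over named variables.

A :class:`DAG` is the structural backbone of every model in this package:
it fixes which variables may directly cause which others.  Nodes are plain
strings; edges are ordered ``(parent, child)`` pairs.  The class is a thin,
validated wrapper around :class:`networkx.DiGraph` with the graph-surgery
helpers that causal inference needs (ancestor/descendant queries, removal
of a treatment's outgoing edges) and text-based import/export (DOT and
two-column edge-list CSV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd


class CycleError(ValueError):
    """Raised when a proposed edge set contains a directed cycle."""


@dataclass(frozen=True)
class DAG:
    """An immutable directed acyclic graph.

    Parameters
    ----------
    nodes:
        Variable names, in a fixed declaration order.
    edges:
        Ordered ``(parent, child)`` pairs; endpoints must be declared nodes
        and the edge set must be acyclic.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    _nx: nx.DiGraph = field(init=False, repr=False, compare=False)

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]] = ()):
        object.__setattr__(self, "nodes", tuple(nodes))
        object.__setattr__(self, "edges", tuple((str(a), str(b)) for a, b in edges))
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        declared = set(self.nodes)
        for a, b in self.edges:
            if a not in declared or b not in declared:
                raise ValueError(f"edge ({a}, {b}) references an undeclared node")
            if a == b:
                raise CycleError(f"self-loop on node {a!r}")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise CycleError(f"edge set contains a directed cycle: {cyc}")
        object.__setattr__(self, "_nx", g)

    # -- queries ---------------------------------------------------------

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(self._nx.predecessors(node)))

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(self._nx.successors(node)))

    def ancestors(self, node: str) -> frozenset[str]:
        return frozenset(nx.ancestors(self._nx, node))

    def descendants(self, node: str) -> frozenset[str]:
        return frozenset(nx.descendants(self._nx, node))

    def topological_order(self) -> tuple[str, ...]:
        # lexicographic tie-break keeps the order reproducible
        return tuple(nx.lexicographical_topological_sort(self._nx))

    def has_edge(self, parent: str, child: str) -> bool:
        return self._nx.has_edge(parent, child)

    def parent_map(self) -> dict[str, tuple[str, ...]]:
        return {v: self.parents(v) for v in self.nodes}

    # -- surgery ---------------------------------------------------------

    def remove_outgoing(self, node: str) -> "DAG":
        """Graph with all edges out of ``node`` deleted (backdoor graph)."""
        return DAG(self.nodes, [(a, b) for a, b in self.edges if a != node])

    def with_edge(self, parent: str, child: str) -> "DAG":
        return DAG(self.nodes, self.edges + ((parent, child),))

    def without_edge(self, parent: str, child: str) -> "DAG":
        return DAG(self.nodes, [e for e in self.edges if e != (parent, child)])

    def directed_paths(self, source: str, target: str) -> list[tuple[str, ...]]:
        """All directed paths from source to target (node sequences)."""
        return [tuple(p) for p in nx.all_simple_paths(self._nx, source, target)]

    def to_networkx(self) -> nx.DiGraph:
        return self._nx.copy()

    # -- text I/O --------------------------------------------------------

    def to_dot(self) -> str:
        lines = ["digraph G {"]
        lines += [f'  "{v}";' for v in self.nodes]
        lines += [f'  "{a}" -> "{b}";' for a, b in self.edges]
        lines.append("}")
        return "\n".join(lines) + "\n"

    def to_edgelist(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.edges), columns=["parent", "child"])

    def write_dot(self, path: str | Path) -> None:
        Path(path).write_text(self.to_dot())

    def write_edgelist(self, path: str | Path) -> None:
        self.to_edgelist().to_csv(path, index=False)

    @classmethod
    def from_edgelist(
        cls, frame: pd.DataFrame, nodes: Iterable[str] | None = None
    ) -> "DAG":
        edges = [(str(a), str(b)) for a, b in frame.itertuples(index=False)]
        if nodes is None:
            seen: list[str] = []
            for a, b in edges:
                for v in (a, b):
                    if v not in seen:
                        seen.append(v)
            nodes = seen
        return cls(nodes, edges)

    @classmethod
    def read_edgelist(cls, path: str | Path, nodes: Iterable[str] | None = None) -> "DAG":
        return cls.from_edgelist(pd.read_csv(path), nodes=nodes)

    @classmethod
    def read_dot(cls, path: str | Path) -> "DAG":
        """Parse the restricted DOT dialect written by :meth:`to_dot`."""
        nodes: list[str] = []
        edges: list[tuple[str, str]] = []
        for raw in Path(path).read_text().splitlines():
            line = raw.strip().rstrip(";")
            if not line or line.startswith(("digraph", "}")):
                continue
            if "->" in line:
                a, b = (part.strip().strip('"') for part in line.split("->"))
                edges.append((a, b))
                for v in (a, b):
                    if v not in nodes:
                        nodes.append(v)
            else:
                v = line.strip('"')
                if v not in nodes:
                    nodes.append(v)
        return cls(nodes, edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DAG):
            return NotImplemented
        return set(self.nodes) == set(other.nodes) and set(self.edges) == set(other.edges)

    def __hash__(self) -> int:
        return hash((frozenset(self.nodes), frozenset(self.edges)))
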