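"""DBN structure representation and single-edge structure-MCMC moves.

Edges point from a node at time t-1 to a node at time t, so the unrolled
graph is bipartite and acyclicity never needs checking.  The graph prior is
uniform over all structures whose in-degrees respect the fan-in bound (and,
optionally, contain no self-loops); invalid graphs are never proposed, so the
prior ratio inside the acceptance probability is identically one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Graph", "neighbourhood", "neighbourhood_size",
           "propose_structure_move", "log_structure_acceptance"]


@dataclass(frozen=True)
class Graph:
    """Directed lag-one network over ``n_nodes`` variables.

    ``edges`` is a frozenset of (source, target) index pairs; ``fan_in_bound``
    caps each node's parent count; self-loops (i, i) model autocorrelation
    and are allowed only when ``allow_self_loops`` is set.
    """

    n_nodes: int
    edges: frozenset = field(default_factory=frozenset)
    fan_in_bound: int = 3
    allow_self_loops: bool = True

    def __post_init__(self) -> None:
        counts = {}
        for (i, j) in self.edges:
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(f"edge ({i},{j}) out of range")
            if i == j and not self.allow_self_loops:
                raise ValueError(f"self-loop ({i},{i}) not allowed")
            counts[j] = counts.get(j, 0) + 1
            if counts[j] > self.fan_in_bound:
                raise ValueError(f"node {j} exceeds fan-in {self.fan_in_bound}")

    def parents(self, node: int) -> tuple[int, ...]:
        return tuple(sorted(i for (i, j) in self.edges if j == node))

    def has_edge(self, i: int, j: int) -> bool:
        return (i, j) in self.edges

    def with_edge_added(self, i: int, j: int) -> "Graph":
        return Graph(self.n_nodes, self.edges | {(i, j)},
                     self.fan_in_bound, self.allow_self_loops)

    def with_edge_removed(self, i: int, j: int) -> "Graph":
        return Graph(self.n_nodes, self.edges - {(i, j)},
                     self.fan_in_bound, self.allow_self_loops)

    @staticmethod
    def empty(n_nodes: int, fan_in_bound: int = 3,
              allow_self_loops: bool = True) -> "Graph":
        return Graph(n_nodes, frozenset(), fan_in_bound, allow_self_loops)


def _candidate_additions(graph: Graph) -> list[tuple[int, int]]:
    adds = []
    for j in range(graph.n_nodes):
        parents = graph.parents(j)
        if len(parents) >= graph.fan_in_bound:
            continue
        for i in range(graph.n_nodes):
            if i == j and not graph.allow_self_loops:
                continue
            if (i, j) not in graph.edges:
                adds.append((i, j))
    return adds


def neighbourhood(graph: Graph) -> list[Graph]:
    """All valid graphs reachable by one edge deletion or one edge addition."""
    out = [graph.with_edge_removed(i, j) for (i, j) in sorted(graph.edges)]
    out.extend(graph.with_edge_added(i, j)
               for (i, j) in _candidate_additions(graph))
    return out


def neighbourhood_size(graph: Graph) -> int:
    """|N(G)| without materialising the neighbourhood."""
    n = graph.n_nodes
    allowed = n if graph.allow_self_loops else n - 1
    size = len(graph.edges)
    for j in range(n):
        p = len(graph.parents(j))
        if p < graph.fan_in_bound:
            size += allowed - p
    return size


def propose_structure_move(graph: Graph, rng: np.random.Generator) -> Graph:
    """Uniform draw from the one-edge neighbourhood of ``graph``."""
    dels = sorted(graph.edges)
    adds = _candidate_additions(graph)
    total = len(dels) + len(adds)
    if total == 0:
        raise RuntimeError("empty structure-move neighbourhood")
    idx = int(rng.integers(total))
    if idx < len(dels):
        return graph.with_edge_removed(*dels[idx])
    return graph.with_edge_added(*adds[idx - len(dels)])


def log_structure_acceptance(log_score_current: float,
                             log_score_candidate: float,
                             current: Graph, candidate: Graph) -> float:
    """Log Metropolis-Hastings acceptance probability for a single-edge move
    under the uniform fan-in-restricted graph prior (prior ratio 1):
    min{0, score ratio + log |N(current)| - log |N(candidate)|}."""
    log_ratio = (log_score_candidate - log_score_current
                 + np.log(neighbourhood_size(current))
                 - np.log(neighbourhood_size(candidate)))
    return min(0.0, log_ratio)
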