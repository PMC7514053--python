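"""Seeded synthetic graphs with PPI-like structure, plus toy fixtures.

Real interactomes are sparse, modular and heavy-tailed in degree.  Two
generators cover those regimes for testing without any download:

* a stochastic block model (SBM), whose p_in / p_out gap gives a
  controllable link-prediction signal (held-out within-block edges are
  recoverable from community structure), and
* a duplication-divergence process, the classic model of proteome growth
  by gene duplication, which produces the heavy-tailed degree
  distributions that exercise degree normalization.

The toy fixtures are the tiny hand-checkable graphs used throughout the
unit tests (single edge, path, cycle, K4 minus an edge, star, a single
length-3 path).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import Graph

__all__ = ["SbmSpec", "DdSpec", "sbm_graph", "duplication_divergence_graph", "toy_fixtures"]


@dataclass(frozen=True)
class SbmSpec:
    """Stochastic block model: within-block prob p_in, cross-block p_out."""

    block_sizes: tuple[int, ...] = (50, 50)
    p_in: float = 0.25
    p_out: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.block_sizes):
            raise ValueError("block sizes must be >= 1")
        for p in (self.p_in, self.p_out):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")


@dataclass(frozen=True)
class DdSpec:
    """Duplication-divergence growth: retain parent edges w.p. p_retain,
    link copy to parent w.p. p_new, until n_final nodes."""

    n_final: int = 100
    p_retain: float = 0.4
    p_new: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_final < 2:
            raise ValueError("n_final must be >= 2")
        for p in (self.p_retain, self.p_new):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")


def sbm_graph(spec: SbmSpec) -> Graph:
    """Independent Bernoulli edges: p_in within a block, p_out across."""
    rng = np.random.default_rng(spec.seed)
    sizes = list(spec.block_sizes)
    n = sum(sizes)
    block = np.repeat(np.arange(len(sizes)), sizes)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            p = spec.p_in if block[i] == block[j] else spec.p_out
            if rng.random() < p:
                edges.append((i, j))
    labels = [f"b{block[i]}_n{i}" for i in range(n)]
    return Graph.from_edges(labels, edges)


def duplication_divergence_graph(spec: DdSpec) -> Graph:
    """Grow from a single edge by duplicating uniform random nodes."""
    rng = np.random.default_rng(spec.seed)
    adj: list[set[int]] = [{1}, {0}]
    while len(adj) < spec.n_final:
        parent = int(rng.integers(len(adj)))
        new = len(adj)
        nbrs = {u for u in adj[parent] if rng.random() < spec.p_retain}
        if rng.random() < spec.p_new:
            nbrs.add(parent)
        adj.append(set(nbrs))
        for u in nbrs:
            adj[u].add(new)
    edges = [(i, j) for i in range(len(adj)) for j in adj[i] if i < j]
    labels = [f"p{i}" for i in range(spec.n_final)]
    return Graph.from_edges(labels, edges)


def toy_fixtures() -> dict[str, Graph]:
    """Named hand-checkable graphs used in worked examples and tests."""
    return {
        "pair": Graph.from_edges(["a", "b"], [(0, 1)]),
        "p3": Graph.from_edges(["a", "b", "c"], [(0, 1), (1, 2)]),
        "c4": Graph.from_edges(["a", "b", "c", "d"], [(0, 1), (1, 2), (2, 3), (3, 0)]),
        "k4_minus_edge": Graph.from_edges(
            ["n0", "n1", "n2", "n3"],
            [(0, 1), (0, 2), (0, 3), (1, 2), (2, 3)],  # all of K4 except (1, 3)
        ),
        "star3": Graph.from_edges(["a", "b", "c", "h"], [(0, 3), (1, 3), (2, 3)]),
        "l3_path": Graph.from_edges(["x", "z1", "z2", "y"], [(0, 1), (1, 2), (2, 3)]),
    }
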