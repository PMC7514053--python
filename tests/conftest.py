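import numpy as np
import pytest

from hovgae.graph import Graph
from hovgae.synthetic import SbmSpec, sbm_graph, toy_fixtures


@pytest.fixture(scope="session")
def toys():
    return toy_fixtures()


@pytest.fixture
def er_graph():
    """Factory for seeded Erdos-Renyi graphs used as oracle instances."""

    def make(n: int, p: float, seed: int) -> Graph:
        rng = np.random.default_rng(seed)
        edges = [(i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p]
        return Graph.from_edges([f"n{i}" for i in range(n)], edges)

    return make


@pytest.fixture(scope="session")
def sbm_two_block():
    """The standard two-community test bed (50+50 nodes)."""
    return sbm_graph(SbmSpec(block_sizes=(50, 50), p_in=0.25, p_out=0.02, seed=0))
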