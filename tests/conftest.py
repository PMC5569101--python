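from __future__ import annotations

import numpy as np
import pytest

from signet.core import Labeling, Sign, SignedGraph


@pytest.fixture
def fork_graph() -> SignedGraph:
    """A activates B and inhibits C; A is the single input."""
    return SignedGraph.from_edges([("A", "B", "+"), ("A", "C", "-")], genes={"B", "C"})


@pytest.fixture
def chain_graph() -> SignedGraph:
    """A -(+)-> B -(+)-> C, all observable."""
    return SignedGraph.from_edges(
        [("A", "B", "+"), ("B", "C", "+")], genes={"A", "B", "C"}
    )


def random_signed_graph(
    rng: np.random.Generator,
    n_nodes: int = 6,
    p_edge: float = 0.25,
    p_inhibition: float = 0.4,
    p_observed: float = 0.5,
) -> tuple[SignedGraph, Labeling]:
    """Small random instance with a random (not necessarily consistent) labeling."""
    names = [f"v{i}" for i in range(n_nodes)]
    edges = []
    for u in names:
        for v in names:
            if u != v and rng.random() < p_edge:
                sign = "-" if rng.random() < p_inhibition else "+"
                edges.append((u, v, sign))
    genes = {n for n in names if rng.random() < p_observed}
    graph = SignedGraph.from_edges(edges, genes=genes, nodes=names)
    signs = [Sign.PLUS, Sign.MINUS, Sign.ZERO]
    beta = Labeling(
        "random", {n: signs[rng.integers(3)] for n in sorted(genes)}
    )
    return graph, beta
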