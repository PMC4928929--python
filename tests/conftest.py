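"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from grnevo import GeneNetwork, SynthConfig, generate

INF = float("inf")


def floyd_warshall(nodes: list[str], arcs) -> dict[tuple[str, str], float]:
    """Hand-rolled all-pairs hop distances: d[(target, source)].

    Independent of the scipy BFS used by the implementation.
    """
    d = {(i, j): (0.0 if i == j else INF) for i in nodes for j in nodes}
    for u, v in arcs:
        d[(v, u)] = 1.0
    for k in nodes:
        for j in nodes:
            djk = d[(k, j)]
            if djk == INF:
                continue
            for i in nodes:
                alt = djk + d[(i, k)]
                if alt < d[(i, j)]:
                    d[(i, j)] = alt
    return d


def random_digraph(rng: np.random.Generator, n: int, p: float = 0.2,
                   undirected_frac: float = 0.3) -> GeneNetwork:
    """Random partially directed network over n gene symbols."""
    names = [f"N{i:02d}" for i in range(n)]
    g = GeneNetwork()
    for nm in names:
        g.add_node(nm)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                und = rng.random() < undirected_frac
                u, v = (i, j) if rng.random() < 0.5 else (j, i)
                g.add_edge(names[u], names[v],
                           weight=float(np.round(rng.uniform(0.5, 2.0), 3)),
                           directed=not und)
    return g


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic bundle shared across read-only tests."""
    return generate(SynthConfig(seed=42))
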