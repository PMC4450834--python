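"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ontosim import toy
from ontosim.ontology import Concept, OntologyGraph


@pytest.fixture(scope="session")
def liver() -> OntologyGraph:
    """The hand-encoded liver-finding hierarchy fragment."""
    return toy.liver_hierarchy()


@pytest.fixture
def chain3() -> OntologyGraph:
    """Minimal 3-concept chain: C is-a B is-a A."""
    return OntologyGraph(
        [Concept("A", "A"), Concept("B", "B"), Concept("C", "C")],
        [("B", "A"), ("C", "B")],
    )


def random_dag(n_nodes: int, seed: int, max_parents: int = 2) -> OntologyGraph:
    """Random rooted DAG: node i > 0 picks 1..max_parents parents among 0..i-1.

    Construction guarantees acyclicity, a unique root (node 0), and a path
    from every node to the root.
    """
    rng = np.random.default_rng(seed)
    concepts = [Concept(f"n{i}", f"node {i}") for i in range(n_nodes)]
    edges = []
    for i in range(1, n_nodes):
        k = int(rng.integers(1, max_parents + 1))
        parents = rng.choice(i, size=min(k, i), replace=False)
        edges.extend((f"n{i}", f"n{p}") for p in parents)
    return OntologyGraph(concepts, edges)


def brute_force_upward_distance(graph: OntologyGraph, start: str, target: str):
    """Oracle: exhaustive DFS over all simple upward paths; min edge count.

    Returns the minimum path length or None when no upward path exists.
    Independent of the shortest-path machinery under test.
    """
    if start == target:
        return 0
    best = [None]

    def dfs(node: str, length: int, seen: frozenset):
        for parent in graph.parents(node):
            if parent in seen:
                continue
            if parent == target:
                if best[0] is None or length + 1 < best[0]:
                    best[0] = length + 1
            dfs(parent, length + 1, seen | {parent})

    dfs(start, 0, frozenset({start}))
    return best[0]


def brute_force_auroc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Oracle: mean over all (positive, negative) pairs of I[s+ > s-] + 0.5 ties."""
    pos = scores[positive]
    neg = scores[~positive]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
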