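"""Shared fixtures and small graph/partition oracles used across tests."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from perconet.network import Partition, WeightedNetwork


@pytest.fixture
def two_triangles() -> WeightedNetwork:
    """Two disjoint unit-weight triangles on nodes 0-2 and 3-5."""
    return WeightedNetwork.from_edges(
        6, [(0, 1, 1), (1, 2, 1), (0, 2, 1), (3, 4, 1), (4, 5, 1), (3, 5, 1)]
    )


@pytest.fixture
def two_triangles_partition() -> Partition:
    return Partition(np.array([0, 0, 0, 1, 1, 1]))


@pytest.fixture
def cliques_with_bridge() -> WeightedNetwork:
    """Two unit-weight 4-cliques joined by a single bridge edge."""
    edges = [
        (i, j, 1.0) for i, j in itertools.combinations(range(4), 2)
    ] + [
        (i, j, 1.0) for i, j in itertools.combinations(range(4, 8), 2)
    ] + [(3, 4, 1.0)]
    return WeightedNetwork.from_edges(8, edges)


@pytest.fixture
def three_node_path() -> WeightedNetwork:
    """Path A-B (0.9), B-C (0.5)."""
    return WeightedNetwork.from_edges(3, [(0, 1, 0.9), (1, 2, 0.5)])


def set_partitions(n: int):
    """All set partitions of range(n) as contiguous label arrays
    (restricted-growth-string enumeration)."""

    def rec(i: int, labels: np.ndarray, k: int):
        if i == n:
            yield labels.copy()
            return
        for c in range(k):
            labels[i] = c
            yield from rec(i + 1, labels, k)
        labels[i] = k
        yield from rec(i + 1, labels, k + 1)

    yield from rec(0, np.zeros(n, dtype=np.int64), 0)


def random_weighted_graph(
    rng: np.random.Generator, n: int, p: float = 0.5
) -> WeightedNetwork:
    """Erdos-Renyi graph with U(0.1, 1) weights; guaranteed >= 1 edge."""
    edges = [
        (i, j, float(rng.uniform(0.1, 1.0)))
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    if not edges:
        edges = [(0, 1, 1.0)]
    return WeightedNetwork.from_edges(n, edges)
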