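"""Core containers: weighted undirected networks and node partitions.

A :class:`WeightedNetwork` is a symmetric, non-negative weighted graph over
nodes ``0..N-1`` stored as a canonical edge list (``i < j``, sorted). It is
the object that gets thresholded, clustered and evaluated. A
:class:`Partition` assigns every node to exactly one community; labels are
contiguous integers starting at 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import MembershipError, ParameterError, ShapeError


@dataclass(frozen=True, eq=False)
class WeightedNetwork:
    """Undirected weighted graph with nodes ``0..n_nodes-1``.

    Edges are stored once with ``edges_i < edges_j``; weights are finite and
    non-negative; self-loops are rejected.
    """

    n_nodes: int
    edges_i: np.ndarray
    edges_j: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ParameterError("network needs at least one node")
        ei = np.asarray(self.edges_i, dtype=np.int64)
        ej = np.asarray(self.edges_j, dtype=np.int64)
        w = np.asarray(self.weights, dtype=np.float64)
        if not (ei.shape == ej.shape == w.shape):
            raise ShapeError("edge arrays must have identical length")
        if ei.size:
            if ei.min() < 0 or ej.max() >= self.n_nodes:
                raise ParameterError("edge endpoint outside node range")
            if np.any(ei >= ej):
                raise ParameterError("edges must satisfy i < j (no self-loops)")
            if not np.all(np.isfinite(w)) or np.any(w < 0):
                raise ParameterError("weights must be finite and non-negative")
        object.__setattr__(self, "edges_i", ei)
        object.__setattr__(self, "edges_j", ej)
        object.__setattr__(self, "weights", w)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_edges(
        cls, n_nodes: int, edges: Iterable[tuple[int, int, float]]
    ) -> "WeightedNetwork":
        """Build from an iterable of ``(i, j, weight)``; orientation and
        duplicates (same weight) are normalized, self-loops rejected."""
        seen: dict[tuple[int, int], float] = {}
        for i, j, w in edges:
            if i == j:
                raise ParameterError(f"self-loop on node {i}")
            a, b = (i, j) if i < j else (j, i)
            if (a, b) in seen and not np.isclose(seen[(a, b)], w):
                raise ParameterError(f"conflicting duplicate edge ({a},{b})")
            seen[(a, b)] = float(w)
        if seen:
            keys = sorted(seen)
            ei = np.array([k[0] for k in keys], dtype=np.int64)
            ej = np.array([k[1] for k in keys], dtype=np.int64)
            w = np.array([seen[k] for k in keys], dtype=np.float64)
        else:
            ei = ej = np.empty(0, dtype=np.int64)
            w = np.empty(0, dtype=np.float64)
        return cls(n_nodes, ei, ej, w)

    @classmethod
    def from_adjacency(
        cls, matrix: np.ndarray, *, tol: float = 1e-10
    ) -> "WeightedNetwork":
        """Build from a dense symmetric adjacency matrix; the diagonal is
        ignored, entries ≤ 0 are treated as absent edges."""
        a = np.asarray(matrix, dtype=np.float64)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ShapeError("adjacency matrix must be square")
        if not np.allclose(a, a.T, atol=tol):
            raise ShapeError("adjacency matrix must be symmetric")
        iu, ju = np.triu_indices(a.shape[0], k=1)
        w = a[iu, ju]
        keep = w > 0
        return cls(a.shape[0], iu[keep], ju[keep], w[keep])

    # -- views ------------------------------------------------------------

    @property
    def n_edges(self) -> int:
        return int(self.weights.size)

    def total_weight(self) -> float:
        return float(self.weights.sum())

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(d, self.edges_i, 1)
        np.add.at(d, self.edges_j, 1)
        return d

    def strengths(self) -> np.ndarray:
        s = np.zeros(self.n_nodes, dtype=np.float64)
        np.add.at(s, self.edges_i, self.weights)
        np.add.at(s, self.edges_j, self.weights)
        return s

    def to_adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=np.float64)
        a[self.edges_i, self.edges_j] = self.weights
        a[self.edges_j, self.edges_i] = self.weights
        return a

    def adjacency_dict(self) -> list[dict[int, float]]:
        """Neighbor map per node (both directions)."""
        adj: list[dict[int, float]] = [dict() for _ in range(self.n_nodes)]
        for i, j, w in zip(self.edges_i, self.edges_j, self.weights):
            adj[int(i)][int(j)] = float(w)
            adj[int(j)][int(i)] = float(w)
        return adj

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from(
            zip(self.edges_i.tolist(), self.edges_j.tolist(), self.weights.tolist())
        )
        return g

    def to_igraph(self):
        import igraph as ig

        g = ig.Graph(
            n=self.n_nodes,
            edges=list(zip(self.edges_i.tolist(), self.edges_j.tolist())),
        )
        g.es["weight"] = self.weights.tolist()
        return g

    def induced(self, nodes: Sequence[int]) -> tuple["WeightedNetwork", np.ndarray]:
        """Subgraph induced on ``nodes`` with relabeling to ``0..len-1``.

        Returns the subgraph and the array of original node ids (new id k
        corresponds to original ``mapping[k]``).
        """
        keep = np.asarray(sorted(set(int(n) for n in nodes)), dtype=np.int64)
        pos = -np.ones(self.n_nodes, dtype=np.int64)
        pos[keep] = np.arange(keep.size)
        mask = (pos[self.edges_i] >= 0) & (pos[self.edges_j] >= 0)
        net = WeightedNetwork(
            keep.size,
            pos[self.edges_i[mask]],
            pos[self.edges_j[mask]],
            self.weights[mask],
        )
        return net, keep

    def equals(self, other: "WeightedNetwork") -> bool:
        return (
            self.n_nodes == other.n_nodes
            and np.array_equal(self.edges_i, other.edges_i)
            and np.array_equal(self.edges_j, other.edges_j)
            and np.array_equal(self.weights, other.weights)
        )


@dataclass(frozen=True, eq=False)
class Partition:
    """Node → community assignment with contiguous labels ``0..k-1``."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.int64)
        if lab.ndim != 1 or lab.size == 0:
            raise ParameterError("partition labels must be a non-empty 1-d array")
        uniq = np.unique(lab)
        if uniq[0] != 0 or uniq[-1] != uniq.size - 1:
            raise ParameterError(
                "labels must be contiguous integers starting at 0; "
                "use Partition.from_labels to normalize"
            )
        object.__setattr__(self, "labels", lab)

    @classmethod
    def from_labels(cls, labels: Sequence[int]) -> "Partition":
        """Normalize arbitrary hashable labels to contiguous ints in order of
        first appearance."""
        lab = list(labels)
        remap: dict = {}
        out = np.empty(len(lab), dtype=np.int64)
        for idx, v in enumerate(lab):
            if v not in remap:
                remap[v] = len(remap)
            out[idx] = remap[v]
        return cls(out)

    @classmethod
    def from_communities(
        cls, communities: Iterable[Iterable[int]], n_nodes: int
    ) -> "Partition":
        out = -np.ones(n_nodes, dtype=np.int64)
        for c, members in enumerate(communities):
            for v in members:
                if out[v] != -1:
                    raise ParameterError(f"node {v} assigned twice")
                out[v] = c
        if np.any(out < 0):
            raise ParameterError("some nodes unassigned")
        return cls(out)

    @property
    def n_nodes(self) -> int:
        return int(self.labels.size)

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_communities)

    def communities(self) -> list[np.ndarray]:
        order = np.argsort(self.labels, kind="stable")
        return list(
            np.split(order, np.cumsum(self.sizes())[:-1])
        )

    def relabel_by_size(self) -> "Partition":
        """Relabel communities in decreasing size order (ties: old label)."""
        sizes = self.sizes()
        order = np.argsort(-sizes, kind="stable")
        remap = np.empty_like(order)
        remap[order] = np.arange(order.size)
        return Partition(remap[self.labels])

    def equals(self, other: "Partition") -> bool:
        return np.array_equal(self.labels, other.labels)

    def same_clustering(self, other: "Partition") -> bool:
        """True if the two partitions are identical up to relabeling."""
        if self.n_nodes != other.n_nodes:
            return False
        return Partition.from_labels(self.labels).equals(
            Partition.from_labels(other.labels)
        )


def require_cover(network: WeightedNetwork, partition: Partition) -> None:
    if partition.n_nodes != network.n_nodes:
        raise MembershipError(
            f"partition covers {partition.n_nodes} nodes, "
            f"network has {network.n_nodes}"
        )


# -- plain-text I/O -------------------------------------------------------


def write_edgelist_tsv(network: WeightedNetwork, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "node_i": network.edges_i,
            "node_j": network.edges_j,
            "weight": network.weights,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_edgelist_tsv(path: str | Path, n_nodes: int | None = None) -> WeightedNetwork:
    df = pd.read_csv(path, sep="\t")
    if n_nodes is None:
        n_nodes = int(max(df["node_i"].max(), df["node_j"].max())) + 1 if len(df) else 1
    return WeightedNetwork.from_edges(
        n_nodes, zip(df["node_i"], df["node_j"], df["weight"])
    )


def write_adjacency_csv(network: WeightedNetwork, path: str | Path) -> None:
    a = network.to_adjacency()
    pd.DataFrame(a, columns=[str(i) for i in range(network.n_nodes)]).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_adjacency_csv(path: str | Path) -> WeightedNetwork:
    a = pd.read_csv(path).to_numpy(dtype=float)
    return WeightedNetwork.from_adjacency(a)


def write_partition_tsv(partition: Partition, path: str | Path) -> None:
    pd.DataFrame(
        {"node_id": np.arange(partition.n_nodes), "community_id": partition.labels}
    ).to_csv(path, sep="\t", index=False)


def read_partition_tsv(path: str | Path) -> Partition:
    df = pd.read_csv(path, sep="\t").sort_values("node_id")
    if not np.array_equal(df["node_id"].to_numpy(), np.arange(len(df))):
        raise ParameterError("partition file must cover node ids 0..N-1")
    return Partition.from_labels(df["community_id"].to_numpy())
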