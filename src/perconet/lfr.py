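"""Weighted LFR benchmark generation with planted community structure.

Generates networks whose node degrees and community sizes follow truncated
power laws, with a topological mixing parameter mu_t (per-node fraction of
edges leaving the community) and a weight mixing parameter mu_w (per-node
fraction of strength on those edges). Node strength follows s_i = k_i**beta.

Construction: degrees and community sizes are sampled from truncated power
laws (the degree-law lower cutoff is solved numerically so the expected mean
equals the requested average degree); nodes are assigned to communities so
that each node's internal degree fits inside its community; intra- and
inter-community stubs are matched separately (configuration-model pairing
with rewiring repair of self/duplicate/intra-violating pairs); edge weights
split each node's strength between internal and external edges in the
(1-mu_w)/mu_w proportion.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .errors import ConvergenceError, ParameterError
from .network import Partition, WeightedNetwork, require_cover
from .percolation import giant_component

logger = logging.getLogger(__name__)

_MEAN_DEGREE_RTOL = 0.02  # accept sampled degree sequences within ±2% of <k>
_MAX_SEQUENCE_ATTEMPTS = 100
_MIXING_TOL = 0.05
_GIANT_FRACTION = 0.95


@dataclass(frozen=True)
class LFRParams:
    """Parameters of the weighted LFR benchmark.

    ``degree_exponent`` and ``community_exponent`` are the power-law
    exponents of the degree and community-size distributions;
    ``mixing_topology`` (mu_t) and ``mixing_weight`` (mu_w) control how many
    edges, and how much strength, each node shares outside its community;
    ``strength_exponent`` (beta) sets node strength as degree**beta.
    """

    n_nodes: int = 600
    degree_exponent: float = 2.0
    community_exponent: float = 1.0
    avg_degree: float = 12.0
    max_degree: int = 50
    min_community: int = 5
    max_community: int = 50
    mixing_topology: float = 0.2
    mixing_weight: float = 0.2
    strength_exponent: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.mixing_topology <= 1.0):
            raise ParameterError("mixing_topology must lie in [0, 1]")
        if not (0.0 <= self.mixing_weight <= 1.0):
            raise ParameterError("mixing_weight must lie in [0, 1]")
        if not (1 <= self.min_community <= self.max_community <= self.n_nodes):
            raise ParameterError("need min_community <= max_community <= n_nodes")
        if not (1.0 <= self.avg_degree <= self.max_degree < self.n_nodes):
            raise ParameterError("need 1 <= avg_degree <= max_degree < n_nodes")
        if self.degree_exponent <= 1.0:
            raise ParameterError("degree_exponent must exceed 1")
        if self.community_exponent < 1.0:
            raise ParameterError("community_exponent must be >= 1")


# -- truncated power laws -------------------------------------------------


def _powerlaw_mean(exponent: float, a: float, b: float) -> float:
    """Mean of the continuous density ∝ x**(-exponent) on [a, b]."""
    if np.isclose(a, b):
        return a
    if np.isclose(exponent, 1.0):
        return (b - a) / np.log(b / a)
    if np.isclose(exponent, 2.0):
        return np.log(b / a) / (1.0 / a - 1.0 / b)
    p1, p2 = 1.0 - exponent, 2.0 - exponent
    return ((b**p2 - a**p2) / p2) / ((b**p1 - a**p1) / p1)


def _powerlaw_sample(
    rng: np.random.Generator, exponent: float, a: float, b: float, size: int
) -> np.ndarray:
    """Inverse-CDF sampling of the truncated continuous power law."""
    u = rng.random(size)
    if np.isclose(exponent, 1.0):
        return a * (b / a) ** u
    p = 1.0 - exponent
    return (a**p + u * (b**p - a**p)) ** (1.0 / p)


def _solve_degree_cutoff(params: LFRParams) -> float:
    """Lower cutoff of the degree law whose mean equals avg_degree."""
    f = lambda a: _powerlaw_mean(params.degree_exponent, a, params.max_degree) - (
        params.avg_degree
    )
    lo, hi = 1.0, float(params.max_degree)
    if f(lo) > 0 or f(hi) < 0:
        raise ParameterError(
            "avg_degree unreachable for the given degree_exponent and max_degree"
        )
    return brentq(f, lo, hi, xtol=1e-10)


def _sample_degrees(rng: np.random.Generator, params: LFRParams) -> np.ndarray:
    kmin = _solve_degree_cutoff(params)
    for _ in range(_MAX_SEQUENCE_ATTEMPTS):
        k = np.rint(
            _powerlaw_sample(rng, params.degree_exponent, kmin, params.max_degree,
                             params.n_nodes)
        ).astype(np.int64)
        k = np.clip(k, 1, params.max_degree)
        if abs(k.mean() - params.avg_degree) <= _MEAN_DEGREE_RTOL * params.avg_degree:
            if k.sum() % 2:  # make total stub count even
                v = int(np.argmin(k)) if k.max() == params.max_degree else int(
                    np.argmax(k < params.max_degree)
                )
                k[v] += 1 if k[v] < params.max_degree else -1
            return k
    raise ConvergenceError(
        f"could not sample a degree sequence with mean within "
        f"{_MEAN_DEGREE_RTOL:.0%} of {params.avg_degree}"
    )


def _sample_community_sizes(
    rng: np.random.Generator, params: LFRParams
) -> np.ndarray:
    n = params.n_nodes
    for _ in range(_MAX_SEQUENCE_ATTEMPTS * 10):
        sizes: list[int] = []
        while sum(sizes) < n:
            s = int(
                np.rint(
                    _powerlaw_sample(
                        rng,
                        params.community_exponent,
                        params.min_community,
                        params.max_community,
                        1,
                    )[0]
                )
            )
            sizes.append(int(np.clip(s, params.min_community, params.max_community)))
        excess = sum(sizes) - n
        sizes.sort(reverse=True)
        idx = 0
        while excess > 0 and any(s > params.min_community for s in sizes):
            room = sizes[idx] - params.min_community
            take = min(room, excess)
            sizes[idx] -= take
            excess -= take
            idx = (idx + 1) % len(sizes)
        if excess == 0:
            return np.array(sorted(sizes, reverse=True), dtype=np.int64)
    raise ParameterError(
        "community sizes in [min_community, max_community] cannot tile n_nodes"
    )


# -- node → community assignment -----------------------------------------


def _assign_communities(
    rng: np.random.Generator,
    degrees: np.ndarray,
    sizes: np.ndarray,
    internal: np.ndarray,
) -> np.ndarray:
    """Random assignment honoring internal-degree feasibility: a node with
    internal degree d needs a community of size > d. Full communities evict a
    random member (standard LFR procedure)."""
    n = degrees.size
    n_comm = sizes.size
    membership = -np.ones(n, dtype=np.int64)
    fill: list[list[int]] = [[] for _ in range(n_comm)]
    queue = deque(rng.permutation(n).tolist())
    cap = 200 * n
    it = 0
    while queue:
        it += 1
        if it > cap:
            raise ConvergenceError("community assignment did not converge")
        v = queue.popleft()
        c = int(rng.integers(n_comm))
        if internal[v] > sizes[c] - 1:
            queue.append(v)
            continue
        if len(fill[c]) < sizes[c]:
            fill[c].append(v)
            membership[v] = c
        else:
            out = fill[c][int(rng.integers(len(fill[c])))]
            fill[c].remove(out)
            membership[out] = -1
            queue.append(out)
            fill[c].append(v)
            membership[v] = c
    return membership


# -- stub matching --------------------------------------------------------


def _pair_stubs(
    rng: np.random.Generator,
    stubs: np.ndarray,
    forbidden_same: np.ndarray | None,
    max_rounds: int = 200,
) -> list[tuple[int, int]]:
    """Randomly pair stubs into edges, repairing self-loops, duplicates and
    (optionally) pairs whose endpoints share a group given by
    ``forbidden_same``. Irreparable pairs are dropped after ``max_rounds``.
    """
    stubs = stubs.copy()
    rng.shuffle(stubs)
    if stubs.size % 2:
        stubs = stubs[:-1]
    pairs = stubs.reshape(-1, 2)
    for _ in range(max_rounds):
        a, b = pairs[:, 0], pairs[:, 1]
        bad = a == b
        if forbidden_same is not None:
            bad |= forbidden_same[a] == forbidden_same[b]
        key_lo = np.minimum(a, b)
        key_hi = np.maximum(a, b)
        order = np.lexsort((key_hi, key_lo))
        dup = np.zeros(pairs.shape[0], dtype=bool)
        same = (np.diff(key_lo[order]) == 0) & (np.diff(key_hi[order]) == 0)
        dup[order[1:][same]] = True
        bad |= dup
        n_bad = int(bad.sum())
        if n_bad == 0:
            break
        # reshuffle the bad pairs' stubs together with as many random good pairs
        good_idx = np.nonzero(~bad)[0]
        extra = good_idx[
            rng.permutation(good_idx.size)[: min(n_bad, good_idx.size)]
        ]
        recycle = np.concatenate([np.nonzero(bad)[0], extra])
        pool = pairs[recycle].ravel()
        rng.shuffle(pool)
        pairs[recycle] = pool.reshape(-1, 2)
    else:
        # drop whatever is still bad
        a, b = pairs[:, 0], pairs[:, 1]
        bad = a == b
        if forbidden_same is not None:
            bad |= forbidden_same[a] == forbidden_same[b]
        key = np.stack([np.minimum(a, b), np.maximum(a, b)], axis=1)
        _, first = np.unique(key, axis=0, return_index=True)
        dup = np.ones(pairs.shape[0], dtype=bool)
        dup[first] = False
        bad |= dup
        pairs = pairs[~bad]
    return [(int(min(p)), int(max(p))) for p in pairs]


def _havel_hakimi(
    nodes: np.ndarray, degs: np.ndarray
) -> list[tuple[int, int]] | None:
    """Simple graph realizing the degree sequence, or None if not graphical."""
    residual = [(int(d), int(v)) for d, v in zip(degs, nodes) if d > 0]
    edges: list[tuple[int, int]] = []
    while residual:
        residual.sort(reverse=True)
        d, v = residual.pop(0)
        if d > len(residual):
            return None
        for idx in range(d):
            du, u = residual[idx]
            edges.append((min(u, v), max(u, v)))
            residual[idx] = (du - 1, u)
        residual = [e for e in residual if e[0] > 0]
    return edges


def _randomize_edges(
    rng: np.random.Generator, edges: list[tuple[int, int]], n_swaps: int
) -> set[tuple[int, int]]:
    """Degree-preserving double-edge swaps; rejects self-loops/duplicates."""
    edge_set = set(edges)
    edge_list = list(edge_set)
    m = len(edge_list)
    if m < 2:
        return edge_set
    for _ in range(n_swaps):
        ia, ib = rng.integers(m, size=2)
        if ia == ib:
            continue
        (a, b), (c, d) = edge_list[ia], edge_list[ib]
        if rng.random() < 0.5:
            p, q = (min(a, c), max(a, c)), (min(b, d), max(b, d))
        else:
            p, q = (min(a, d), max(a, d)), (min(b, c), max(b, c))
        if p[0] == p[1] or q[0] == q[1] or p in edge_set or q in edge_set:
            continue
        edge_set.remove((a, b))
        edge_set.remove((c, d))
        edge_set.add(p)
        edge_set.add(q)
        edge_list[ia], edge_list[ib] = p, q
    return edge_set


def _build_edges(
    rng: np.random.Generator,
    degrees: np.ndarray,
    membership: np.ndarray,
    internal: np.ndarray,
) -> tuple[set[tuple[int, int]], set[tuple[int, int]]]:
    """Realize intra-community degree sequences exactly (Havel-Hakimi plus
    randomizing double-edge swaps) and match inter-community stubs globally;
    returns (intra_edges, inter_edges) as i<j tuples."""
    n_comm = int(membership.max()) + 1
    internal = internal.copy()
    intra_edges: set[tuple[int, int]] = set()
    for c in range(n_comm):
        members = np.nonzero(membership == c)[0]
        for _ in range(members.size * 4 + 8):
            ints = internal[members]
            if ints.sum() % 2:  # fix parity by shifting one stub
                sz = members.size
                cand = members[(ints < sz - 1) & (ints < degrees[members])]
                if cand.size:
                    v = int(cand[int(rng.integers(cand.size))])
                    internal[v] += 1
                else:
                    cand = members[ints > 0]
                    v = int(cand[int(rng.integers(cand.size))])
                    internal[v] -= 1
                ints = internal[members]
            edges = _havel_hakimi(members, ints)
            if edges is not None:
                break
            # not graphical: shed one stub from the largest internal degree
            v = int(members[int(np.argmax(ints))])
            internal[v] -= 1
        else:
            raise ConvergenceError(f"community {c}: internal degrees not realizable")
        intra_edges.update(_randomize_edges(rng, edges, 10 * len(edges)))
    external = degrees - internal
    if external.sum() % 2:
        cand = np.nonzero(external > 0)[0]
        v = int(cand[int(rng.integers(cand.size))])
        external[v] -= 1
    stubs = np.repeat(np.arange(degrees.size), external)
    inter_edges = set(_pair_stubs(rng, stubs, membership))
    inter_edges -= intra_edges
    return intra_edges, inter_edges


# -- weights --------------------------------------------------------------


def _assign_weights(
    intra: list[tuple[int, int]],
    inter: list[tuple[int, int]],
    degrees: np.ndarray,
    params: LFRParams,
) -> list[tuple[int, int, float]]:
    """Split each node's target strength k**beta between internal and
    external incident edges in proportion (1-mu_w) : mu_w; an edge takes the
    average of its two endpoints' per-edge shares."""
    n = degrees.size
    kint = np.zeros(n, dtype=np.int64)
    kext = np.zeros(n, dtype=np.int64)
    for i, j in intra:
        kint[i] += 1
        kint[j] += 1
    for i, j in inter:
        kext[i] += 1
        kext[j] += 1
    k = kint + kext
    strength = np.where(k > 0, k.astype(float) ** params.strength_exponent, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        share_int = np.where(
            kint > 0, (1.0 - params.mixing_weight) * strength / kint, 0.0
        )
        share_ext = np.where(kext > 0, params.mixing_weight * strength / kext, 0.0)
    out: list[tuple[int, int, float]] = []
    for i, j in intra:
        out.append((i, j, 0.5 * (share_int[i] + share_int[j])))
    for i, j in inter:
        out.append((i, j, 0.5 * (share_ext[i] + share_ext[j])))
    return out


# -- public API -----------------------------------------------------------


def empirical_mixing(
    network: WeightedNetwork, partition: Partition
) -> tuple[float, float]:
    """Measured (mu_t, mu_w): mean over non-isolated nodes of the fraction of
    degree, respectively strength, on edges leaving the node's community."""
    require_cover(network, partition)
    lab = partition.labels
    deg = network.degrees().astype(float)
    stren = network.strengths()
    ext_deg = np.zeros(network.n_nodes)
    ext_str = np.zeros(network.n_nodes)
    cross = lab[network.edges_i] != lab[network.edges_j]
    np.add.at(ext_deg, network.edges_i[cross], 1.0)
    np.add.at(ext_deg, network.edges_j[cross], 1.0)
    np.add.at(ext_str, network.edges_i[cross], network.weights[cross])
    np.add.at(ext_str, network.edges_j[cross], network.weights[cross])
    active = deg > 0
    mu_t = float(np.mean(ext_deg[active] / deg[active])) if active.any() else 0.0
    pos = stren > 0
    mu_w = float(np.mean(ext_str[pos] / stren[pos])) if pos.any() else 0.0
    return mu_t, mu_w


def generate_lfr(params: LFRParams) -> tuple[WeightedNetwork, Partition]:
    """Generate a weighted LFR benchmark and its planted partition.

    The returned network is connected (restricted to its giant component when
    that covers >= 95% of nodes, regenerated otherwise); with mu_t = 0 the
    communities are intentionally mutually disconnected and no such filtering
    applies. Community labels are ordered by decreasing size.
    """
    params.validate()
    root = np.random.SeedSequence(params.seed)
    last_mu = None
    for attempt in range(20):
        rng = np.random.default_rng(root.spawn(1)[0] if attempt else root)
        try:
            net, part = _generate_once(rng, params)
        except ConvergenceError:
            continue
        mu_t_hat, _ = empirical_mixing(net, part)
        last_mu = mu_t_hat
        if abs(mu_t_hat - params.mixing_topology) <= _MIXING_TOL:
            return net, part
    raise ConvergenceError(
        f"could not reach target mixing {params.mixing_topology} within "
        f"tolerance {_MIXING_TOL}; achieved mu_t = {last_mu}"
    )


def _generate_once(
    rng: np.random.Generator, params: LFRParams
) -> tuple[WeightedNetwork, Partition]:
    degrees = _sample_degrees(rng, params)
    sizes = _sample_community_sizes(rng, params)
    # stochastic rounding keeps the expected per-node internal fraction at
    # exactly 1 - mu_t (deterministic rounding biases the realized mixing)
    exact = (1.0 - params.mixing_topology) * degrees
    internal = np.floor(exact).astype(np.int64)
    internal += (rng.random(degrees.size) < (exact - internal)).astype(np.int64)
    internal = np.minimum(internal, degrees)
    # a node can never have more internal partners than the largest community
    internal = np.minimum(internal, sizes.max() - 1)
    membership = _assign_communities(rng, degrees, sizes, internal)
    intra, inter = _build_edges(rng, degrees, membership, internal)
    if params.mixing_topology == 0.0:
        # parity/graphicality repairs may have shed stubs to the external
        # pool; at exact zero mixing those are dropped, not externalized
        inter = set()
    weighted = _assign_weights(sorted(intra), sorted(inter), degrees, params)
    net = WeightedNetwork.from_edges(params.n_nodes, weighted)
    part = Partition.from_labels(membership)

    if params.mixing_topology > 0:
        size, nodes = giant_component(net)
        if size < _GIANT_FRACTION * params.n_nodes:
            raise ConvergenceError(
                f"giant component covers only {size}/{params.n_nodes} nodes"
            )
        if size < params.n_nodes:
            logger.info("restricting to giant component (%d nodes)", size)
            net, keep = net.induced(sorted(nodes))
            part = Partition.from_labels(part.labels[keep])
    return net, part.relabel_by_size()
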