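import itertools

import numpy as np
import pytest

from perconet.community import (
    asymptotical_surprise,
    detect,
    infomap_adapter,
    louvain,
    modularity,
    paco,
)
from perconet.errors import (
    BackendNotAvailableError,
    DegenerateInputError,
    ParameterError,
)
from perconet.network import Partition, WeightedNetwork

from conftest import random_weighted_graph, set_partitions


class TestModularity:
    def test_single_community_scores_zero(self, cliques_with_bridge):
        part = Partition(np.zeros(8, dtype=np.int64))
        assert modularity(cliques_with_bridge, part).value == pytest.approx(0.0)

    def test_two_triangles_hand_value(self, two_triangles, two_triangles_partition):
        assert modularity(two_triangles, two_triangles_partition).value == (
            pytest.approx(0.5)
        )

    def test_k4_pair_split_hand_value(self):
        k4 = WeightedNetwork.from_edges(
            4, [(i, j, 1.0) for i, j in itertools.combinations(range(4), 2)]
        )
        part = Partition(np.array([0, 0, 1, 1]))
        assert modularity(k4, part).value == pytest.approx(-1 / 6)

    def test_matches_networkx_on_random_graphs(self):
        import networkx as nx

        rng = np.random.default_rng(21)
        for _ in range(20):
            g = random_weighted_graph(rng, int(rng.integers(4, 15)))
            labels = rng.integers(0, 3, size=g.n_nodes)
            part = Partition.from_labels(labels)
            comms = [set(np.nonzero(part.labels == c)[0].tolist())
                     for c in range(part.n_communities)]
            ref = nx.community.modularity(g.to_networkx(), comms, weight="weight")
            assert modularity(g, part).value == pytest.approx(ref, abs=1e-12)

    def test_edgeless_network_rejected(self):
        with pytest.raises(DegenerateInputError):
            modularity(WeightedNetwork.from_edges(3, []),
                       Partition(np.zeros(3, dtype=np.int64)))


class TestSurpriseScore:
    def test_single_community_scores_zero(self, two_triangles):
        s = asymptotical_surprise(two_triangles, Partition(np.zeros(6, dtype=np.int64)))
        assert s.value == 0.0
        assert s.q == s.q_expected == 1.0

    def test_two_triangles_closed_form(self, two_triangles, two_triangles_partition):
        s = asymptotical_surprise(two_triangles, two_triangles_partition)
        assert s.q == pytest.approx(1.0)
        assert s.q_expected == pytest.approx(0.4)
        assert s.value == pytest.approx(6 * np.log(2.5), abs=1e-12)

    def test_all_singletons_score_zero(self, two_triangles):
        s = asymptotical_surprise(two_triangles, Partition(np.arange(6)))
        assert s.value == 0.0

    def test_observed_at_expected_density_scores_zero(self):
        # complete graph with uniform weights: q always equals <q>'s weight
        # share for the balanced bisection of K4
        k4 = WeightedNetwork.from_edges(
            4, [(i, j, 1.0) for i, j in itertools.combinations(range(4), 2)]
        )
        part = Partition(np.array([0, 0, 1, 1]))
        s = asymptotical_surprise(k4, part)
        assert s.q == pytest.approx(s.q_expected)
        assert s.value == 0.0

    def test_label_and_node_permutation_invariance(self, two_triangles):
        rng = np.random.default_rng(3)
        part = Partition(np.array([0, 0, 1, 1, 2, 2]))
        base = asymptotical_surprise(two_triangles, part).value
        relabel = Partition.from_labels((part.labels + 1) % 3)
        assert asymptotical_surprise(two_triangles, relabel).value == (
            pytest.approx(base, abs=1e-12)
        )
        perm = rng.permutation(6)
        pnet = WeightedNetwork.from_edges(
            6,
            [(int(perm[i]), int(perm[j]), w) for i, j, w in
             zip(two_triangles.edges_i, two_triangles.edges_j,
                 two_triangles.weights)],
        )
        ppart = Partition.from_labels(part.labels[np.argsort(perm)])
        assert asymptotical_surprise(pnet, ppart).value == (
            pytest.approx(base, abs=1e-12)
        )


class TestLouvain:
    def test_separates_bridged_cliques(self, cliques_with_bridge):
        part = louvain(cliques_with_bridge, seed=0)
        assert part.same_clustering(Partition(np.array([0] * 4 + [1] * 4)))

    def test_single_clique_stays_whole(self):
        k4 = WeightedNetwork.from_edges(
            4, [(i, j, 1.0) for i, j in itertools.combinations(range(4), 2)]
        )
        assert louvain(k4, seed=0).n_communities == 1

    def test_deterministic(self, cliques_with_bridge):
        a = louvain(cliques_with_bridge, seed=5, n_restarts=3)
        b = louvain(cliques_with_bridge, seed=5, n_restarts=3)
        assert a.equals(b)

    def test_never_below_single_community_baseline(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            g = random_weighted_graph(rng, 10)
            part = louvain(g, seed=0, n_restarts=4)
            assert modularity(g, part).value >= 0.0

    def test_attains_exhaustive_maximum_usually(self):
        rng = np.random.default_rng(42)
        hits = 0
        for trial in range(50):
            n = int(rng.integers(4, 9))
            g = random_weighted_graph(rng, n)
            best = max(
                modularity(g, Partition(lab)).value for lab in set_partitions(n)
            )
            got = modularity(g, louvain(g, seed=trial)).value
            hits += abs(got - best) < 1e-12
        assert hits >= 45

    def test_agrees_with_igraph_multilevel_quality(self, cliques_with_bridge):
        import igraph  # independent optimizer as cross-check

        g = cliques_with_bridge.to_igraph()
        ref = g.community_multilevel(weights="weight")
        ours = louvain(cliques_with_bridge, seed=0)
        assert modularity(cliques_with_bridge, ours).value == pytest.approx(
            ref.modularity, abs=1e-12
        )


class TestPaco:
    def test_recovers_two_triangles(self, two_triangles, two_triangles_partition):
        assert paco(two_triangles, seed=0).same_clustering(two_triangles_partition)

    def test_recovers_bridged_cliques(self, cliques_with_bridge):
        part = paco(cliques_with_bridge, seed=0)
        assert part.same_clustering(Partition(np.array([0] * 4 + [1] * 4)))

    def test_deterministic(self, cliques_with_bridge):
        a = paco(cliques_with_bridge, seed=9, n_trials=4)
        b = paco(cliques_with_bridge, seed=9, n_trials=4)
        assert a.equals(b)

    def test_attains_exhaustive_maximum_usually(self):
        rng = np.random.default_rng(7)
        hits = 0
        for trial in range(50):
            n = int(rng.integers(4, 8))
            g = random_weighted_graph(rng, n)
            best = max(
                asymptotical_surprise(g, Partition(lab)).value
                for lab in set_partitions(n)
            )
            got = asymptotical_surprise(g, paco(g, seed=trial)).value
            hits += abs(got - best) < 1e-9
        assert hits >= 45

    def test_never_below_trivial_partitions(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            g = random_weighted_graph(rng, 9)
            got = asymptotical_surprise(g, paco(g, seed=1, n_trials=4)).value
            assert got >= 0.0


class TestInfomapAdapter:
    def test_two_triangles_split(self, two_triangles, two_triangles_partition):
        part = infomap_adapter(two_triangles, seed=0)
        assert part.same_clustering(two_triangles_partition)

    def test_unknown_backend_raises_configuration_error(self, two_triangles):
        with pytest.raises(BackendNotAvailableError, match="backend"):
            infomap_adapter(two_triangles, backend="not-a-backend")

    def test_igraph_round_trip_preserves_network(self, cliques_with_bridge):
        g = cliques_with_bridge.to_igraph()
        back = WeightedNetwork.from_edges(
            g.vcount(),
            [(e.source, e.target, e["weight"]) for e in g.es],
        )
        assert back.equals(cliques_with_bridge)


class TestDetectDispatch:
    def test_unknown_method_rejected(self, two_triangles):
        with pytest.raises(ParameterError):
            detect("walktrap", two_triangles)

    @pytest.mark.parametrize("method", ["newman", "surprise", "infomap"])
    def test_all_methods_cover_all_nodes(self, method, cliques_with_bridge):
        part = detect(method, cliques_with_bridge, seed=0,
                      n_restarts=4, n_trials=4)
        assert part.n_nodes == 8
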