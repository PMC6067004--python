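"""Weighted seeded cluster expansion and complex detection."""

import itertools
import math

import networkx as nx
import pytest

from mlpr.complexes import (build_seed_queue, detect_clusters,
                            detect_complexes, expand_cluster,
                            interaction_probability, vertex_weights)


def _graph(*edges):
    g = nx.Graph()
    for a, b, w in edges:
        g.add_edge(a, b, weight=w)
    return g


class TestVertexWeights:
    def test_isolated_vertex(self):
        g = nx.Graph()
        g.add_node("x")
        assert vertex_weights(g)["x"] == 0.0

    def test_incident_sum(self):
        g = _graph(("a", "b", 0.2), ("a", "c", 0.3))
        assert vertex_weights(g)["a"] == pytest.approx(0.5)

    def test_unit_weights_reduce_to_degree(self):
        g = nx.path_graph(5)
        nx.set_edge_attributes(g, 1.0, "weight")
        w = vertex_weights(g)
        assert all(w[v] == g.degree(v) for v in g)


class TestSeedQueue:
    def test_weight_order(self):
        q = build_seed_queue({"a": 3, "b": 1, "c": 2},
                             {"a": 1, "b": 1, "c": 1})
        assert q == ["a", "c", "b"]

    def test_degree_breaks_weight_ties(self):
        q = build_seed_queue({"a": 1.0, "b": 1.0}, {"a": 2, "b": 5})
        assert q == ["b", "a"]

    def test_full_tie_falls_back_to_id(self):
        q = build_seed_queue({"z": 1.0, "a": 1.0}, {"z": 2, "a": 2})
        assert q == ["a", "z"]


class TestInteractionProbability:
    def test_no_edge_into_cluster(self):
        g = _graph(("a", "b", 1.0), ("c", "d", 1.0))
        assert interaction_probability("c", {"a", "b"}, g) == 0.0

    def test_hand_ratio(self):
        g = _graph(("a", "b", 3.0), ("a", "v", 1.0), ("b", "v", 0.5))
        assert interaction_probability("v", {"a", "b"}, g) == pytest.approx(0.5)

    def test_ratio_identity(self):
        w = 0.7
        g = _graph(("a", "b", w), ("a", "v", w / 2), ("b", "v", w / 2))
        assert interaction_probability("v", {"a", "b"}, g) == pytest.approx(1.0)

    def test_singleton_cluster_sentinel(self):
        g = _graph(("s", "v", 0.4))
        assert interaction_probability("v", {"s"}, g) == math.inf


class TestExpandCluster:
    def test_seed_with_no_qualifying_neighbor(self):
        g = _graph(("s", "v", 1.0), ("v", "w", 1.0))
        # after v joins, w's ratio is 1/1 = 1, so use T_in > 1 via weights:
        cluster = expand_cluster("s", g, T_in=0.6, d=1)
        # d=1 forbids any non-adjacent growth beyond the first triangle-free add
        assert "s" in cluster.members

    def test_four_clique_full_recovery(self):
        """Admission ratios run inf, 2/1, 3/3 = 1.0, all >= T_in=0.6."""
        g = nx.complete_graph(4)
        g = nx.relabel_nodes(g, {i: f"v{i}" for i in range(4)})
        nx.set_edge_attributes(g, 1.0, "weight")
        cluster = expand_cluster("v0", g, T_in=0.6, d=2)
        assert cluster.members == frozenset(g.nodes)
        ratios = [e for _, e in cluster.admissions]
        assert ratios[0] == math.inf
        assert ratios[1] == pytest.approx(2.0)
        assert ratios[2] == pytest.approx(1.0)

    def test_path_growth_stops_at_diameter(self):
        """Seeding b on a-b-c-d admits a and c; d is excluded (T_in=0 so
        only the diameter bound 2 can reject it, at diameter 3)."""
        g = _graph(("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0))
        cluster = expand_cluster("b", g, T_in=0.0, d=2)
        assert cluster.members == frozenset({"a", "b", "c"})

    def test_admissions_respect_threshold(self):
        g = nx.complete_graph(6)
        g = nx.relabel_nodes(g, {i: f"v{i}" for i in range(6)})
        nx.set_edge_attributes(g, 1.0, "weight")
        cluster = expand_cluster("v0", g, T_in=0.6, d=2)
        for _, e in cluster.admissions[1:]:
            assert e >= 0.6
        # the 6th member would arrive at ratio 5/10 = 0.5 < 0.6
        assert len(cluster.members) == 5

    def test_skip_singleton_seed_mode(self):
        g = _graph(("s", "v", 1.0))
        cluster = expand_cluster("s", g, skip_singleton_seed=True)
        assert cluster.members == frozenset({"s"})


class TestDetectComplexes:
    def test_two_disjoint_cliques(self):
        g = nx.Graph()
        for offset, names in ((0, "abcd"), (1, "wxyz")):
            for u, v in itertools.combinations(names, 2):
                g.add_edge(u, v, weight=1.0)
        found = detect_complexes(g, T_in=0.6, d=2, min_complex_size=3)
        assert {frozenset("abcd"), frozenset("wxyz")} == set(found)

    def test_empty_network(self):
        assert len(detect_complexes(nx.Graph())) == 0

    def test_degenerate_threshold_yields_nothing(self):
        g = _graph(("a", "b", 0.1), ("c", "d", 0.1))
        assert len(detect_complexes(g, T_in=1.0, min_complex_size=3)) == 0

    def test_determinism(self):
        rng_edges = [(f"n{i}", f"n{(i * 7 + 3) % 20}", 0.1 + (i % 5) / 10)
                     for i in range(40) if i != (i * 7 + 3) % 20]
        g = _graph(*rng_edges)
        a = detect_complexes(g).complexes
        b = detect_complexes(g).complexes
        assert a == b

    def test_emitted_clusters_connected_within_diameter(self):
        import numpy as np

        rng = np.random.default_rng(2)
        g = nx.gnp_random_graph(30, 0.2, seed=2)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.random())
        d = 2
        for cluster in detect_clusters(g, T_in=0.3, d=d, min_complex_size=3):
            sub = g.subgraph(cluster.members)
            assert nx.is_connected(sub)
            assert nx.diameter(sub) <= d
            # every admission met the threshold at its time
            for _, e in cluster.admissions:
                assert e >= 0.3 or e == math.inf

    @pytest.mark.parametrize("size,n_cliques,T_in", [(4, 3, 0.6), (6, 4, 0.4)])
    def test_clique_union_recovery_matches_components(self, size, n_cliques,
                                                      T_in):
        """On a disjoint union of uniform cliques, detection recovers the
        cliques exactly (oracle: connected components); full recovery needs
        T_in <= 2/(size-1) since the m-th member arrives at ratio 2/(m-1)."""
        assert T_in <= 2 / (size - 1)
        g = nx.Graph()
        for c in range(n_cliques):
            names = [f"c{c}m{i}" for i in range(size)]
            for u, v in itertools.combinations(names, 2):
                g.add_edge(u, v, weight=1.0)
        assert g.number_of_nodes() <= 30
        oracle = {frozenset(comp) for comp in nx.connected_components(g)}
        found = set(detect_complexes(g, T_in=T_in, d=2).complexes)
        assert found == oracle

    def test_overlap_flag(self):
        # bowtie: two triangles sharing vertex m
        g = _graph(("a", "b", 1.0), ("a", "m", 1.0), ("b", "m", 1.0),
                   ("x", "y", 1.0), ("x", "m", 1.0), ("y", "m", 1.0))
        with_overlap = detect_complexes(g, T_in=0.5, d=2, allow_overlap=True)
        without = detect_complexes(g, T_in=0.5, d=2, allow_overlap=False)
        assert any(
            len(set(c1) & set(c2)) > 0
            for i, c1 in enumerate(with_overlap)
            for c2 in list(with_overlap)[i + 1:]) or len(with_overlap) == 1
        flat = [p for c in without for p in c]
        assert len(flat) == len(set(flat))  # no protein reused
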