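"""Cohesion metrics against independent brute-force oracles."""

from __future__ import annotations

import math
from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import mk_net, random_digraph
from sownet.metrics import (
    arc_reciprocity,
    betweenness,
    clustering_weighted_overall,
    components_isolates,
    degree_centralization,
    density,
    kcore_assign,
    summarize,
)

# ---------------------------------------------------------------------------
# independent oracles


def brute_betweenness(net):
    """Exhaustive geodesic enumeration on the directed binary graph."""
    nodes = list(net.nodes)
    succ = {u: [] for u in nodes}
    for (u, v) in net.arcs:
        succ[u].append(v)

    def all_paths(s, t, length):
        # depth-first enumeration of all s->t paths of exactly `length` arcs
        if length == 0:
            return [[s]] if s == t else []
        out = []
        for nxt in succ[s]:
            for rest in all_paths(nxt, t, length - 1):
                out.append([s] + rest)
        return out

    def bfs_dist(s):
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in succ[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        return dist

    score = dict.fromkeys(nodes, 0.0)
    for s in nodes:
        dist = bfs_dist(s)
        for t, d in dist.items():
            if t == s or d < 2:
                continue
            geodesics = all_paths(s, t, d)
            for path in geodesics:
                for v in path[1:-1]:
                    score[v] += 1.0 / len(geodesics)
    return score


def brute_coreness(net):
    """Iterative pruning reimplemented with plain dict adjacency."""
    adj = {u: set() for u in net.nodes}
    for (u, v) in net.arcs:
        adj[u].add(v)
        adj[v].add(u)
    core = {}
    k = 0
    remaining = dict(adj)
    while remaining:
        while True:
            doomed = [v for v, nb in remaining.items() if len(nb) <= k]
            if not doomed:
                break
            for v in doomed:
                core[v] = k
                for w in remaining[v]:
                    if w in remaining:
                        remaining[w].discard(v)
                del remaining[v]
        k += 1
    return core


# ---------------------------------------------------------------------------


class TestDensity:
    def test_directed_cycle_half_density(self):
        assert density(mk_net([("A", "B"), ("B", "C"), ("C", "A")])) == pytest.approx(0.5)

    def test_complete_digraph_is_one(self):
        nodes = list("ABCD")
        net = mk_net([(u, v) for u in nodes for v in nodes if u != v])
        assert density(net) == pytest.approx(1.0)

    def test_fifteen_percent_of_potential_ties(self, rng):
        # 57 arcs among 20*19 = 380 possible ordered ties -> density 0.15
        nodes = [f"N{i}" for i in range(20)]
        pairs = [(u, v) for u in nodes for v in nodes if u != v]
        chosen = rng.choice(len(pairs), size=57, replace=False)
        net = mk_net([pairs[i] for i in chosen], nodes=nodes)
        assert density(net) == pytest.approx(0.15)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            density(mk_net({}, nodes=["A"]))


class TestReciprocity:
    def test_all_mutual_is_one(self):
        assert arc_reciprocity(mk_net([("A", "B"), ("B", "A")])) == pytest.approx(1.0)

    def test_no_mutual_is_zero(self):
        assert arc_reciprocity(mk_net([("A", "B"), ("A", "C")])) == pytest.approx(0.0)

    def test_two_thirds(self):
        assert arc_reciprocity(mk_net([("A", "B"), ("B", "A"), ("A", "C")])) == pytest.approx(2 / 3)

    def test_no_arcs_is_missing(self):
        assert math.isnan(arc_reciprocity(mk_net({}, nodes=["A", "B"])))


class TestCentralization:
    def test_out_star_is_one(self):
        net = mk_net([("H", v) for v in "ABCD"])
        assert degree_centralization(net, "out") == pytest.approx(1.0)

    def test_directed_cycle_is_zero_all_directions(self):
        net = mk_net([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        for d in ("in", "out", "total"):
            assert degree_centralization(net, d) == pytest.approx(0.0)

    def test_matches_freeman_formula_from_degree_vector(self, rng):
        net = random_digraph(rng, 30, 0.1)
        g = net.to_networkx()
        for direction, degs, denom in (
            ("in", [g.in_degree(v) for v in g], 29 * 29),
            ("out", [g.out_degree(v) for v in g], 29 * 29),
            ("total", [g.degree(v) for v in g], 2 * 29 * 28),
        ):
            expected = sum(max(degs) - d for d in degs) / denom
            assert degree_centralization(net, direction) == pytest.approx(expected)

    def test_bounded_zero_one(self, rng):
        for _ in range(10):
            net = random_digraph(rng, 12, 0.25)
            for d in ("in", "out", "total"):
                assert 0.0 <= degree_centralization(net, d) <= 1.0


class TestBetweenness:
    def test_middle_of_path_scores_one(self, directed_path):
        b = betweenness(directed_path)
        assert b == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_complete_digraph_all_zero(self):
        nodes = list("ABCDE")
        net = mk_net([(u, v) for u in nodes for v in nodes if u != v])
        assert all(v == 0 for v in betweenness(net).values())

    def test_matches_exhaustive_geodesic_enumeration(self, rng):
        for _ in range(5):
            net = random_digraph(rng, 12, 0.2)
            got = betweenness(net)
            want = brute_betweenness(net)
            for v in net.nodes:
                assert got[v] == pytest.approx(want[v], abs=1e-9)


class TestClustering:
    def test_complete_triad_is_one(self, triangle_mutual):
        assert clustering_weighted_overall(triangle_mutual) == pytest.approx(1.0)

    def test_star_is_zero(self):
        net = mk_net([("H", v) for v in "ABCD"])
        assert clustering_weighted_overall(net) == pytest.approx(0.0)

    def test_no_triples_is_missing(self):
        assert math.isnan(clustering_weighted_overall(mk_net([("A", "B")], nodes=list("ABC"))))

    def test_matches_triple_enumeration(self, rng):
        net = random_digraph(rng, 15, 0.15)
        g = net.symmetrized()
        closed = connected = 0
        for v in g:  # enumerate all triples around each centre v
            for a, b in combinations(list(g.neighbors(v)), 2):
                connected += 1
                closed += int(g.has_edge(a, b))
        assert clustering_weighted_overall(net) == pytest.approx(closed / connected)


class TestComponents:
    def test_single_arc_among_five_nodes(self):
        net = mk_net([("A", "B")], nodes=list("ABCDE"))
        assert components_isolates(net) == (4, 1, 3)

    def test_connected_digraph(self):
        net = mk_net([(f"N{i}", f"N{i+1}") for i in range(9)])
        assert components_isolates(net) == (1, 1, 0)

    def test_matches_union_find(self, rng):
        net = random_digraph(rng, 40, 0.02)
        parent = {v: v for v in net.nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for (u, v) in net.arcs:
            parent[find(u)] = find(v)
        n_comp = len({find(v) for v in net.nodes})
        touched = {a for pair in net.arcs for a in pair}
        n_iso = len(set(net.nodes) - touched)
        roots_nontrivial = {find(v) for v in touched}
        assert components_isolates(net) == (n_comp, len(roots_nontrivial), n_iso)


class TestKCore:
    def test_complete_graph_coreness(self):
        nodes = list("ABCDE")
        net = mk_net([(u, v) for u, v in permutations(nodes, 2)])
        assert set(kcore_assign(net).values()) == {4}

    def test_star_coreness_is_one(self):
        net = mk_net([("H", f"L{i}") for i in range(5)])
        assert set(kcore_assign(net).values()) == {1}

    def test_planted_clique_with_sparse_periphery(self, rng):
        clique = [f"C{i}" for i in range(8)]
        periph = [f"P{i}" for i in range(22)]
        arcs = {(u, v): 1 for u, v in permutations(clique, 2) if u < v}
        for i, p in enumerate(periph):  # sparse chain + a few links into the clique
            if i:
                arcs[(periph[i - 1], p)] = 1
            if i % 5 == 0:
                arcs[(p, clique[i % 8])] = 1
        net = mk_net(arcs, nodes=clique + periph)
        core = kcore_assign(net)
        assert all(core[c] == 7 for c in clique)
        # subgraph-definition check: the 7-core induces min degree >= 7
        g = net.symmetrized()
        seven = [v for v, k in core.items() if k >= 7]
        sub = g.subgraph(seven)
        assert min(dict(sub.degree).values()) >= 7
        assert core == brute_coreness(net)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_core_nesting_and_degree_bound(self, seed):
        net = random_digraph(np.random.default_rng(seed), 20, 0.15)
        core = kcore_assign(net)
        g = net.symmetrized()
        assert all(core[v] <= g.degree(v) for v in net.nodes)
        ks = sorted(set(core.values()))
        shells = [{v for v, c in core.items() if c >= k} for k in ks]
        for bigger, smaller in zip(shells, shells[1:]):
            assert smaller <= bigger


def test_summary_bounded_quantities(rng):
    net = random_digraph(rng, 25, 0.12)
    s = summarize(net)
    for val in (
        s.density,
        s.arc_reciprocity,
        s.centralization_total,
        s.centralization_in,
        s.centralization_out,
        s.clustering_weighted_overall,
    ):
        assert math.isnan(val) or 0.0 <= val <= 1.0
    assert s.n_isolates <= s.n_nodes
    assert s.density == pytest.approx(s.n_arcs / (25 * 24))
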