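"""Group-level cohesion metrics and the k-core decomposition.

All metrics operate on a :class:`~sownet.data.PrefNetwork`. Structural
metrics (density, reciprocity, centralization, betweenness, components,
k-cores) are computed on the binarized directed graph; the overall
clustering coefficient is computed on the symmetrized graph, weighting
each node's local coefficient by its number of neighbour pairs so that
well-connected animals contribute proportionally more (the overall graph
clustering coefficient, equal to the closed-triple / connected-triple
ratio).

Conventions worth noting:

* *Mean degree* is reported both binary (arcs / n) and weighted
  (total arc weight / n); published tables rarely say which they use.
* Betweenness is unnormalized shortest-path betweenness on the directed
  binary graph; a normalized variant is available by flag.
* Coreness comes from iterative pruning of the symmetrized binary graph:
  a node's coreness is the largest k such that it survives pruning at k.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import networkx as nx

from .data import PrefNetwork

__all__ = [
    "NetworkSummary",
    "density",
    "arc_reciprocity",
    "degree_centralization",
    "betweenness",
    "clustering_weighted_overall",
    "components_isolates",
    "kcore_assign",
    "summarize",
]


@dataclass(frozen=True)
class NetworkSummary:
    """One column of the per-threshold network comparison table."""

    threshold_label: str
    n_nodes: int
    n_arcs: int
    n_isolates: int
    n_components: int
    n_nontrivial_components: int
    density: float
    mean_degree_binary: float
    mean_degree_weighted: float
    centralization_total: float
    centralization_in: float
    centralization_out: float
    clustering_weighted_overall: float
    arc_reciprocity: float
    mean_betweenness: float

    def to_dict(self) -> dict:
        return asdict(self)


def density(net: PrefNetwork) -> float:
    """Binary arcs divided by the n(n-1) possible directed ties."""
    n = net.n_nodes
    if n < 2:
        raise ValueError(f"density undefined for n={n} (< 2 nodes)")
    return net.n_arcs / (n * (n - 1))


def arc_reciprocity(net: PrefNetwork) -> float:
    """Fraction of arcs whose reverse arc is also present (NaN if no arcs)."""
    if net.n_arcs == 0:
        return math.nan
    mutual = sum(1 for (u, v) in net.arcs if (v, u) in net.arcs)
    return mutual / net.n_arcs


def _freeman(values: list[float], denom: float) -> float:
    c_max = max(values)
    return sum(c_max - c for c in values) / denom


def degree_centralization(net: PrefNetwork, direction: str = "total") -> float:
    """Freeman degree centralization of the binarized directed graph.

    0 for degree-regular graphs, 1 when one individual dominates. The
    normalizer is the maximum achievable concentration for a directed graph
    of the same size: ``(n-1)^2`` for in or out degree (a perfect one-way
    star), ``2(n-1)(n-2)`` for total degree (a hub tied both ways to every
    other node).
    """
    n = net.n_nodes
    if n < 3:
        raise ValueError(f"centralization undefined for n={n} (< 3 nodes)")
    g = net.to_networkx()
    if direction == "in":
        vals, denom = [d for _, d in g.in_degree()], (n - 1) ** 2
    elif direction == "out":
        vals, denom = [d for _, d in g.out_degree()], (n - 1) ** 2
    elif direction == "total":
        vals, denom = [d for _, d in g.degree()], 2 * (n - 1) * (n - 2)
    else:
        raise ValueError(f"direction must be in/out/total, got {direction!r}")
    return _freeman(vals, denom)


def betweenness(net: PrefNetwork, normalized: bool = False) -> dict[str, float]:
    """Shortest-path betweenness per node on the directed binary graph.

    Animals lying on no geodesic between others score 0.
    """
    g = net.to_networkx()
    return dict(nx.betweenness_centrality(g, normalized=normalized))


def mean_betweenness(net: PrefNetwork, normalized: bool = False) -> float:
    scores = betweenness(net, normalized=normalized)
    return sum(scores.values()) / len(scores) if scores else 0.0


def clustering_weighted_overall(net: PrefNetwork) -> float:
    """Overall clustering on the symmetrized graph, nodes weighted by pairs.

    For each node v with degree d >= 2 in the symmetrized graph, the local
    coefficient cc_v is the fraction of its d(d-1)/2 neighbour pairs that
    are themselves connected; the overall coefficient is
    sum(cc_v * pairs_v) / sum(pairs_v). Returns NaN when no node has two
    neighbours.
    """
    g = net.symmetrized()
    closed = 0
    pairs = 0
    for v in g:
        nbrs = list(g.neighbors(v))
        d = len(nbrs)
        if d < 2:
            continue
        pairs += d * (d - 1) // 2
        closed += sum(
            1
            for i in range(d)
            for j in range(i + 1, d)
            if g.has_edge(nbrs[i], nbrs[j])
        )
    if pairs == 0:
        return math.nan
    return closed / pairs


def components_isolates(net: PrefNetwork) -> tuple[int, int, int]:
    """(weak components, non-singleton components, isolates).

    Isolates are degree-0 nodes and count as singleton components.
    """
    g = net.to_networkx()
    comps = list(nx.weakly_connected_components(g))
    nontrivial = sum(1 for c in comps if len(c) > 1)
    isolates = sum(1 for v in g if g.degree(v) == 0)
    return len(comps), nontrivial, isolates


def kcore_assign(net: PrefNetwork) -> dict[str, int]:
    """Coreness per animal via iterative pruning of the symmetrized graph."""
    g = net.symmetrized()
    return dict(nx.core_number(g))


def summarize(net: PrefNetwork) -> NetworkSummary:
    """All cohesion metrics for one threshold network."""
    n_comp, n_nontrivial, n_iso = components_isolates(net)
    n = net.n_nodes
    return NetworkSummary(
        threshold_label=net.threshold_label,
        n_nodes=n,
        n_arcs=net.n_arcs,
        n_isolates=n_iso,
        n_components=n_comp,
        n_nontrivial_components=n_nontrivial,
        density=density(net) if n >= 2 else math.nan,
        mean_degree_binary=net.n_arcs / n if n else math.nan,
        mean_degree_weighted=net.total_weight / n if n else math.nan,
        centralization_total=degree_centralization(net, "total") if n >= 3 else math.nan,
        centralization_in=degree_centralization(net, "in") if n >= 3 else math.nan,
        centralization_out=degree_centralization(net, "out") if n >= 3 else math.nan,
        clustering_weighted_overall=clustering_weighted_overall(net) if n >= 3 else math.nan,
        arc_reciprocity=arc_reciprocity(net),
        mean_betweenness=mean_betweenness(net),
    )
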