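"""Shared fixtures: tiny constructed networks and random-network helpers."""

from __future__ import annotations

import numpy as np
import pytest

from sownet.data import PrefNetwork


def mk_net(arcs, nodes=None, level: int = 1, label: str | None = None) -> PrefNetwork:
    """Build a network from {(u, v): w} or [(u, v), ...] (weight 1)."""
    if not isinstance(arcs, dict):
        arcs = {pair: 1 for pair in arcs}
    if nodes is None:
        nodes = sorted({a for pair in arcs for a in pair})
    from sownet.data import THRESHOLD_LABELS

    return PrefNetwork(
        nodes=tuple(nodes),
        arcs=arcs,
        threshold_label=label or THRESHOLD_LABELS.get(level, f"min{level}"),
        threshold_level=level,
    )


def random_digraph(rng: np.random.Generator, n: int, p: float, max_weight: int = 5) -> PrefNetwork:
    """Erdos-Renyi style random directed network with integer weights."""
    nodes = [f"N{i}" for i in range(n)]
    arcs = {}
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                arcs[(nodes[i], nodes[j])] = int(rng.integers(1, max_weight + 1))
    return mk_net(arcs, nodes=nodes)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230601)


@pytest.fixture
def triangle_mutual() -> PrefNetwork:
    """Fully mutually connected triad (all six directed arcs)."""
    nodes = ["A", "B", "C"]
    return mk_net({(u, v): 1 for u in nodes for v in nodes if u != v}, nodes=nodes)


@pytest.fixture
def directed_path() -> PrefNetwork:
    return mk_net([("A", "B"), ("B", "C")])
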