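"""Gould-Fernandez brokerage roles within a node partition.

A broker j sits on an *open* ordered two-path i -> j -> k (i != k, no
direct i -> k arc). The partition labels of (i, j, k) decide the role:

==============  =======================================
coordinator     g_i = g_j = g_k (all within the broker's group)
gatekeeper      g_i != g_j and g_j = g_k (external source)
representative  g_i = g_j and g_j != g_k (external sink)
consultant      g_i = g_k != g_j (broker external to both endpoints' group)
liaison         all three labels distinct
==============  =======================================

These five rules are exhaustive and mutually exclusive over label triples.
Raw counts are compared to their expectation under random reassignment of
the partition labels (group sizes fixed, graph fixed), estimated by seeded
Monte-Carlo permutation. The normalized relative score raw/expected forms
a per-animal brokerage profile; the profile's argmax among roles actually
performed assigns the animal's typology. Profiles where a performed role
has zero expectation are flagged ``excluded`` as uninterpretable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .data import PrefNetwork

__all__ = [
    "ROLES",
    "classify_two_path",
    "two_paths",
    "raw_brokerage",
    "expected_brokerage",
    "brokerage_profiles",
    "assign_typology",
    "census",
]

ROLES = ("coordinator", "gatekeeper", "representative", "consultant", "liaison")


def classify_two_path(g_i, g_j, g_k) -> str:
    """Role of broker j on the ordered path i -> j -> k from group labels."""
    if g_i == g_j == g_k:
        return "coordinator"
    if g_i != g_j and g_j == g_k:
        return "gatekeeper"
    if g_i == g_j and g_j != g_k:
        return "representative"
    if g_i == g_k and g_i != g_j:
        return "consultant"
    return "liaison"


def two_paths(net: PrefNetwork, include_closed: bool = False) -> np.ndarray:
    """Ordered open two-paths as an (m, 3) array of node indices (i, j, k).

    A two-path requires arcs i->j and j->k with i != k; by default triples
    closed by a direct i->k arc are excluded (brokering is between two
    otherwise unconnected individuals). ``include_closed=True`` keeps them.
    """
    idx = {a: n for n, a in enumerate(net.nodes)}
    out_nbrs: dict[int, list[int]] = {}
    for (u, v) in net.arcs:
        out_nbrs.setdefault(idx[u], []).append(idx[v])
    arc_set = {(idx[u], idx[v]) for (u, v) in net.arcs}
    triples = []
    for i, js in out_nbrs.items():
        for j in js:
            for k in out_nbrs.get(j, ()):
                if k == i:
                    continue
                if not include_closed and (i, k) in arc_set:
                    continue
                triples.append((i, j, k))
    return np.array(triples, dtype=np.intp).reshape(-1, 3)


def _label_array(net: PrefNetwork, partition: Mapping[str, object]) -> np.ndarray:
    missing = [a for a in net.nodes if a not in partition]
    if missing:
        raise ValueError(f"node(s) without partition label: {missing}")
    lab_list = [partition[a] for a in net.nodes]
    codes = {l: c for c, l in enumerate(dict.fromkeys(lab_list))}
    return np.array([codes[l] for l in lab_list], dtype=np.intp)


def _role_counts(lab: np.ndarray, paths: np.ndarray, n_nodes: int) -> np.ndarray:
    """(n_nodes, 5) raw role counts for one label vector, vectorized."""
    counts = np.zeros((n_nodes, len(ROLES)), dtype=np.intp)
    if len(paths) == 0:
        return counts
    gi, gj, gk = lab[paths[:, 0]], lab[paths[:, 1]], lab[paths[:, 2]]
    role = np.full(len(paths), 4, dtype=np.intp)  # liaison unless matched below
    role[(gi == gj) & (gj == gk)] = 0
    role[(gi != gj) & (gj == gk)] = 1
    role[(gi == gj) & (gj != gk)] = 2
    role[(gi == gk) & (gi != gj)] = 3
    np.add.at(counts, (paths[:, 1], role), 1)
    return counts


def raw_brokerage(
    net: PrefNetwork, partition: Mapping[str, object], include_closed: bool = False
) -> pd.DataFrame:
    """Per-animal raw role counts (columns = the five roles)."""
    lab = _label_array(net, partition)
    counts = _role_counts(lab, two_paths(net, include_closed), net.n_nodes)
    df = pd.DataFrame(counts, index=list(net.nodes), columns=list(ROLES))
    df.index.name = "animal_id"
    return df


def expected_brokerage(
    net: PrefNetwork,
    partition: Mapping[str, object],
    n_perm: int = 1000,
    seed: int = 0,
    include_closed: bool = False,
) -> pd.DataFrame:
    """Monte-Carlo expected role counts under label permutation.

    The two-path inventory is fixed by the graph; only labels are shuffled,
    so the expectation is estimated by re-classifying the same triples
    under ``n_perm`` permuted label vectors.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    lab = _label_array(net, partition)
    paths = two_paths(net, include_closed)
    rng = np.random.default_rng(seed)
    acc = np.zeros((net.n_nodes, len(ROLES)), dtype=float)
    for _ in range(n_perm):
        acc += _role_counts(rng.permutation(lab), paths, net.n_nodes)
    df = pd.DataFrame(acc / n_perm, index=list(net.nodes), columns=list(ROLES))
    df.index.name = "animal_id"
    return df


def assign_typology(raw_row: pd.Series, norm_row: pd.Series) -> str:
    """Typology = role with maximal normalized score among performed roles.

    ``none`` if the animal performed no brokering at all; ``unresolved`` if
    the maximum is tied between roles (ties are reported, never broken).
    """
    performed = raw_row[raw_row > 0]
    if performed.empty:
        return "none"
    scores = norm_row[performed.index].astype(float)
    finite = scores[np.isfinite(scores)]
    if finite.empty:
        return "unresolved"
    top = finite.max()
    winners = finite[finite >= top - 1e-12]
    return str(winners.index[0]) if len(winners) == 1 else "unresolved"


def brokerage_profiles(
    net: PrefNetwork,
    partition: Mapping[str, object],
    n_perm: int = 1000,
    seed: int = 0,
    include_closed: bool = False,
) -> pd.DataFrame:
    """Full per-animal profile: raw, expected, normalized, typology, excluded.

    ``excluded`` marks uninterpretable profiles — a role performed (raw > 0)
    whose permutation expectation is 0, leaving the normalized score
    undefined. Such animals are flagged rather than silently dropped.
    """
    raw = raw_brokerage(net, partition, include_closed)
    exp = expected_brokerage(net, partition, n_perm, seed, include_closed)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = raw.to_numpy(dtype=float) / exp.to_numpy()
    norm_df = pd.DataFrame(norm, index=raw.index, columns=[f"norm_{r}" for r in ROLES])
    out = pd.concat(
        [
            raw.add_prefix("raw_"),
            exp.add_prefix("exp_"),
            norm_df,
        ],
        axis=1,
    )
    typologies, excluded = [], []
    for a in raw.index:
        norm_row = pd.Series(norm_df.loc[a].to_numpy(), index=list(ROLES))
        typologies.append(assign_typology(raw.loc[a], norm_row))
        bad = bool(((raw.loc[a] > 0) & (exp.loc[a] == 0)).any())
        excluded.append(bad)
    out["typology"] = typologies
    out["excluded"] = excluded
    out["group"] = [partition[a] for a in raw.index]
    return out


def census(
    net: PrefNetwork, partition: Mapping[str, object], include_closed: bool = False
) -> pd.DataFrame:
    """Per-subgroup census: total role incidences and role percentages.

    The census count for a subgroup is the sum of its members' raw role
    counts; percentages are each role's share of that total (NaN for a
    subgroup whose members broker nothing).
    """
    raw = raw_brokerage(net, partition, include_closed)
    raw = raw.assign(group=[partition[a] for a in raw.index])
    sums = raw.groupby("group")[list(ROLES)].sum()
    total = sums.sum(axis=1)
    pct = sums.div(total, axis=0) * 100.0
    out = pd.concat([total.rename("census_count"), pct.add_suffix("_pct")], axis=1)
    out["n_members"] = raw.groupby("group").size()
    out.index.name = "group"
    return out.sort_index()
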