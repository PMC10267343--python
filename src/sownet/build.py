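"""Build threshold networks from observation records and compute degrees.

An approach qualifies as a preferential association when it was *tolerated*
for strictly more than 60 seconds. The arc weight for an ordered dyad
(initiator, recipient) is the number of qualifying events over the whole
observation window. Three standard networks come from minimum-weight
thresholds: the original network (level 1), the mean network (level 2) and
the 1.5x-mean network (level 3).

Animals that joined or left the herd mid-cycle were observed for fewer
hours. Their degrees are presence-adjusted under a constant-rate
assumption: the per-hour interaction rate is ``y = n / x`` where ``n`` is
the raw (weighted) degree and ``x`` the hours observed, and the adjusted
degree extrapolates that rate to the full window, ``y * H_total``.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import pandas as pd

from .data import (
    THRESHOLD_LABELS,
    TOTAL_HOURS,
    AnimalRegistry,
    ObservationRecord,
    PrefNetwork,
    ValidationError,
)

__all__ = ["aggregate", "apply_threshold", "adjusted_degrees", "DEGREE_COLUMNS"]

DEGREE_COLUMNS = [
    "in_degree_raw",
    "out_degree_raw",
    "in_degree_binary",
    "out_degree_binary",
    "in_rate",
    "out_rate",
    "in_adjusted",
    "out_adjusted",
    "hours_present",
]


def aggregate(
    records: Iterable[ObservationRecord],
    nodes: Sequence[str] | AnimalRegistry | None = None,
    min_toleration_s: float = 60.0,
) -> PrefNetwork:
    """Count qualifying approaches per ordered dyad into the original network.

    Only records with outcome ``tolerated`` and toleration strictly greater
    than ``min_toleration_s`` contribute. ``nodes`` (typically the registry)
    fixes the node set so non-interacting animals appear as isolates; if
    omitted, the node set is the animals seen in qualifying records plus any
    animal appearing in any record.
    """
    records = list(records)
    counts: Counter[tuple[str, str]] = Counter()
    seen: set[str] = set()
    for r in records:
        seen.update((r.initiator, r.recipient))
        if r.outcome == "tolerated" and r.toleration_s > min_toleration_s:
            counts[(r.initiator, r.recipient)] += 1
    if nodes is None:
        node_tuple = tuple(sorted(seen))
    elif isinstance(nodes, AnimalRegistry):
        node_tuple = tuple(nodes.animal_ids)
    else:
        node_tuple = tuple(nodes)
    node_set = set(node_tuple)
    stray = {a for pair in counts for a in pair} - node_set
    if stray:
        raise ValidationError(f"records mention animals outside the node set: {sorted(stray)}")
    return PrefNetwork(nodes=node_tuple, arcs=dict(counts), threshold_label="original", threshold_level=1)


def apply_threshold(net: PrefNetwork, level: int, drop_isolates: bool = False) -> PrefNetwork:
    """Keep arcs with weight >= ``level``; nodes stay as isolates by default.

    ``drop_isolates=True`` additionally removes nodes left without any arc,
    shrinking the network the way filtered sociograms are often reported.
    """
    if level < 1:
        raise ValidationError(f"threshold level must be >= 1, got {level}")
    arcs = {pair: w for pair, w in net.arcs.items() if w >= level}
    nodes: Sequence[str] = net.nodes
    if drop_isolates:
        connected = {a for pair in arcs for a in pair}
        nodes = tuple(n for n in net.nodes if n in connected)
    label = THRESHOLD_LABELS.get(level, f"min{level}")
    return PrefNetwork(nodes=tuple(nodes), arcs=arcs, threshold_label=label, threshold_level=level)


def adjusted_degrees(
    net: PrefNetwork,
    registry: AnimalRegistry,
    H_total: float = TOTAL_HOURS,
) -> pd.DataFrame:
    """Weighted and binary degrees with presence-adjusted variants.

    Returns a DataFrame indexed by animal_id with raw weighted degrees
    (arc weights summed), binary degrees (distinct partners), per-hour
    rates and adjusted degrees. For an animal present the full ``H_total``
    hours the adjusted degree equals the raw degree exactly.
    """
    hours = registry.hours()
    missing = [n for n in net.nodes if n not in hours]
    if missing:
        raise ValidationError(f"node(s) absent from registry: {missing}")
    rows = {}
    for a in net.nodes:
        rows[a] = dict.fromkeys(DEGREE_COLUMNS, 0.0)
        rows[a]["hours_present"] = hours[a]
    for (u, v), w in net.arcs.items():
        rows[u]["out_degree_raw"] += w
        rows[v]["in_degree_raw"] += w
        rows[u]["out_degree_binary"] += 1
        rows[v]["in_degree_binary"] += 1
    for a, r in rows.items():
        x = r["hours_present"]
        r["in_rate"] = r["in_degree_raw"] / x
        r["out_rate"] = r["out_degree_raw"] / x
        r["in_adjusted"] = r["in_rate"] * H_total
        r["out_adjusted"] = r["out_rate"] * H_total
    df = pd.DataFrame.from_dict(rows, orient="index", columns=DEGREE_COLUMNS)
    df.index.name = "animal_id"
    return df
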