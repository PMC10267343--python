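"""Core record types and file I/O for herd observation data and networks.

The pipeline works from two delimited-text inputs:

* an *observation table* — one row per approach event, with the initiating
  and receiving animal, the observation session it fell in, how long the
  approach was tolerated, and its outcome;
* an *animal registry* — one row per animal with parity, breeding group and
  the number of observation hours the animal was actually present.

Networks are held in :class:`PrefNetwork`, a directed, integer-weighted
graph whose node set is carried independently of the arc list so that
isolates survive filtering. Networks can be exported as edge-list CSV,
GraphML, or full-matrix UCINET DL for external sociogram viewers.

Column schemas are fixed:

* observations: ``day,session,initiator,recipient,toleration_s,outcome``
* registry:     ``animal_id,parity,breeding_group,hours_present``

Files are UTF-8, comma-delimited, ``.`` decimal. Animal identifiers are
opaque strings (ear-tag numbers on the source farm); no numeric semantics
are assumed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "SESSIONS",
    "OUTCOMES",
    "THRESHOLD_LABELS",
    "ObservationRecord",
    "AnimalRegistry",
    "PrefNetwork",
    "read_observations",
    "write_observations",
    "read_registry",
    "write_registry",
    "write_network",
    "read_network",
]


class SchemaError(ValueError):
    """A required column is missing or the file shape is wrong."""


class ValidationError(ValueError):
    """A row or value violates a data invariant."""


#: Daily one-hour observation blocks (08:00-09:00, 15:00-16:00, 20:00-21:00).
SESSIONS = ("morning", "afternoon", "evening")

#: Outcome of an approach. Only "tolerated" events feed the network.
OUTCOMES = ("tolerated", "displaced", "withdrawn")

#: Threshold labels for the three standard networks (minimum arc weight 1, 2, 3).
THRESHOLD_LABELS = {1: "original", 2: "mean", 3: "mean1_5"}

OBSERVATION_COLUMNS = ["day", "session", "initiator", "recipient", "toleration_s", "outcome"]
REGISTRY_COLUMNS = ["animal_id", "parity", "breeding_group", "hours_present"]

#: Observation window length in days and total observed hours.
STUDY_DAYS = 21
TOTAL_HOURS = 21.0


@dataclass(frozen=True)
class ObservationRecord:
    """One initiator-to-recipient approach during an observation session."""

    day: int
    session: str
    initiator: str
    recipient: str
    toleration_s: float
    outcome: str

    def __post_init__(self) -> None:
        if not 1 <= self.day <= STUDY_DAYS:
            raise ValidationError(f"day {self.day} outside study window 1..{STUDY_DAYS}")
        if self.session not in SESSIONS:
            raise ValidationError(f"unknown session {self.session!r}")
        if self.initiator == self.recipient:
            raise ValidationError(f"self-interaction for animal {self.initiator!r}")
        if not self.toleration_s >= 0:
            raise ValidationError(f"negative toleration {self.toleration_s}")
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"unknown outcome {self.outcome!r}")


@dataclass(frozen=True)
class AnimalRegistry:
    """Per-animal attributes: parity (1-6), breeding group (1-7), hours present.

    ``hours_present`` is the number of observation hours the animal was in
    the herd, in ``(0, total_hours]``; animals added or removed mid-cycle
    have fewer hours than the full window.
    """

    table: pd.DataFrame = field(repr=False)
    total_hours: float = TOTAL_HOURS

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in REGISTRY_COLUMNS if c not in t.columns]
        if missing:
            raise SchemaError(f"registry missing column(s): {', '.join(missing)}")
        dup = t["animal_id"][t["animal_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate animal_id: {dup.iloc[0]!r}")
        bad_parity = t.loc[~t["parity"].between(1, 6), "animal_id"]
        if len(bad_parity):
            raise ValidationError(f"parity outside 1..6 for animal {bad_parity.iloc[0]!r}")
        bad_hours = t.loc[(t["hours_present"] <= 0) | (t["hours_present"] > self.total_hours), "animal_id"]
        if len(bad_hours):
            raise ValidationError(
                f"hours_present outside (0, {self.total_hours}] for animal {bad_hours.iloc[0]!r}"
            )

    @property
    def animal_ids(self) -> list[str]:
        return list(self.table["animal_id"])

    def __len__(self) -> int:
        return len(self.table)

    def attribute(self, name: str) -> dict[str, object]:
        """Mapping animal_id -> attribute column (e.g. parity)."""
        return dict(zip(self.table["animal_id"], self.table[name]))

    def hours(self) -> dict[str, float]:
        return {a: float(h) for a, h in zip(self.table["animal_id"], self.table["hours_present"])}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnimalRegistry):
            return NotImplemented
        return (
            self.total_hours == other.total_hours
            and self.table.reset_index(drop=True).equals(other.table.reset_index(drop=True))
        )


@dataclass(frozen=True)
class PrefNetwork:
    """Directed integer-weighted preferential-association network.

    ``nodes`` is carried independently of ``arcs`` so that animals with no
    qualifying tie remain representable as isolates. ``threshold_level`` is
    the minimum interaction count per ordered dyad for an arc to be kept.
    """

    nodes: tuple[str, ...]
    arcs: Mapping[tuple[str, str], int]
    threshold_label: str = "original"
    threshold_level: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "arcs", dict(self.arcs))
        if len(set(self.nodes)) != len(self.nodes):
            raise ValidationError("duplicate node identifiers")
        if self.threshold_level < 1:
            raise ValidationError("threshold_level must be >= 1")
        node_set = set(self.nodes)
        for (u, v), w in self.arcs.items():
            if u == v:
                raise ValidationError(f"self-arc on node {u!r}")
            if u not in node_set or v not in node_set:
                raise ValidationError(f"arc endpoint {u!r}->{v!r} outside node set")
            if not (isinstance(w, (int,)) and w >= self.threshold_level):
                raise ValidationError(
                    f"arc {u!r}->{v!r} weight {w!r} below threshold {self.threshold_level}"
                )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    @property
    def total_weight(self) -> int:
        return sum(self.arcs.values())

    def to_networkx(self) -> nx.DiGraph:
        """Directed graph including isolates; weights on the ``weight`` key."""
        g = nx.DiGraph(threshold_label=self.threshold_label, threshold_level=self.threshold_level)
        g.add_nodes_from(self.nodes)
        for (u, v), w in self.arcs.items():
            g.add_edge(u, v, weight=int(w))
        return g

    def symmetrized(self) -> nx.Graph:
        """Undirected view: edge if an arc exists either way, weight = sum."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (u, v), w in self.arcs.items():
            if g.has_edge(u, v):
                g[u][v]["weight"] += int(w)
            else:
                g.add_edge(u, v, weight=int(w))
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PrefNetwork):
            return NotImplemented
        return (
            set(self.nodes) == set(other.nodes)
            and dict(self.arcs) == dict(other.arcs)
            and self.threshold_label == other.threshold_label
            and self.threshold_level == other.threshold_level
        )


# ---------------------------------------------------------------------------
# Observation and registry I/O


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file missing column(s): {', '.join(missing)}")


def read_observations(path: str | Path) -> list[ObservationRecord]:
    """Read an observation table; every malformed row raises, none are dropped."""
    df = pd.read_csv(path, dtype={"initiator": str, "recipient": str, "session": str, "outcome": str})
    _require_columns(df, OBSERVATION_COLUMNS, "observation")
    records: list[ObservationRecord] = []
    for pos, row in enumerate(df.itertuples(index=False), start=1):
        try:
            toleration = float(row.toleration_s)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"row {pos}: unparseable toleration_s {row.toleration_s!r}") from exc
        try:
            records.append(
                ObservationRecord(
                    day=int(row.day),
                    session=str(row.session),
                    initiator=str(row.initiator),
                    recipient=str(row.recipient),
                    toleration_s=toleration,
                    outcome=str(row.outcome),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {pos}: {exc}") from exc
    return records


def write_observations(records: Iterable[ObservationRecord], path: str | Path) -> None:
    df = pd.DataFrame([r.__dict__ for r in records], columns=OBSERVATION_COLUMNS)
    df.to_csv(path, index=False)


def read_registry(path: str | Path, total_hours: float = TOTAL_HOURS) -> AnimalRegistry:
    df = pd.read_csv(path, dtype={"animal_id": str})
    _require_columns(df, REGISTRY_COLUMNS, "registry")
    df = df[REGISTRY_COLUMNS].copy()
    df["parity"] = df["parity"].astype(int)
    df["breeding_group"] = df["breeding_group"].astype(int)
    df["hours_present"] = df["hours_present"].astype(float)
    return AnimalRegistry(table=df, total_hours=total_hours)


def write_registry(registry: AnimalRegistry, path: str | Path) -> None:
    registry.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Network I/O

NETWORK_FORMATS = ("edgelist_csv", "graphml", "ucinet_dl")


def write_network(net: PrefNetwork, path: str | Path, format: str = "edgelist_csv") -> None:
    """Write a network; ``edgelist_csv`` and ``graphml`` round-trip losslessly.

    ``ucinet_dl`` emits the full-matrix DL dialect with embedded labels for
    import into UCINET or sociogram viewers (export only).
    """
    path = Path(path)
    if format == "edgelist_csv":
        _write_edgelist_csv(net, path)
    elif format == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    elif format == "ucinet_dl":
        _write_ucinet_dl(net, path)
    else:
        raise ValueError(f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}")


def read_network(path: str | Path, format: str = "edgelist_csv") -> PrefNetwork:
    path = Path(path)
    if format == "edgelist_csv":
        return _read_edgelist_csv(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        arcs = {(str(u), str(v)): int(d["weight"]) for u, v, d in g.edges(data=True)}
        return PrefNetwork(
            nodes=tuple(str(n) for n in g.nodes),
            arcs=arcs,
            threshold_label=str(g.graph.get("threshold_label", "original")),
            threshold_level=int(g.graph.get("threshold_level", 1)),
        )
    raise ValueError(f"unknown network format {format!r}; readable formats: edgelist_csv, graphml")


def _write_edgelist_csv(net: PrefNetwork, path: Path) -> None:
    # Metadata and the full node list (isolates included) go in '#' header
    # lines so the arc rows stay a plain 3-column CSV.
    meta = {
        "threshold_label": net.threshold_label,
        "threshold_level": net.threshold_level,
        "nodes": list(net.nodes),
    }
    lines = [f"# sownet-network {json.dumps(meta)}", "initiator,recipient,weight"]
    for (u, v), w in sorted(net.arcs.items()):
        lines.append(f"{u},{v},{int(w)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_edgelist_csv(path: Path) -> PrefNetwork:
    text = path.read_text(encoding="utf-8").splitlines()
    if not text or not text[0].startswith("# sownet-network "):
        raise SchemaError(f"{path} is not a sownet edge-list CSV")
    meta = json.loads(text[0][len("# sownet-network ") :])
    df = pd.read_csv(path, comment="#", dtype={"initiator": str, "recipient": str})
    _require_columns(df, ["initiator", "recipient", "weight"], "edge-list")
    arcs = {
        (str(r.initiator), str(r.recipient)): int(r.weight) for r in df.itertuples(index=False)
    }
    return PrefNetwork(
        nodes=tuple(meta["nodes"]),
        arcs=arcs,
        threshold_label=meta["threshold_label"],
        threshold_level=int(meta["threshold_level"]),
    )


def _write_ucinet_dl(net: PrefNetwork, path: Path) -> None:
    nodes = list(net.nodes)
    n = len(nodes)
    lines = [f"DL n={n} format=fullmatrix", "labels:", ",".join(nodes), "data:"]
    for u in nodes:
        row = [str(net.arcs.get((u, v), 0)) for v in nodes]
        lines.append(" ".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
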