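"""Time-stamped contact data and its conversion to switching snapshots.

An empirical temporal network is a time-ordered list of contact events
(t, u, v).  Splitting the event list in half by event count gives two
unweighted snapshot graphs; when the two halves cover different node sets,
two constructions are available: restrict both snapshots to the common nodes
(method 1), or keep the union of nodes so that nodes absent from one half
become isolated in that snapshot (method 2).  Fixation is impossible on a
static network with isolated nodes, but occurs on the switching network
whenever the aggregate is connected.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from pathlib import Path

import numpy as np

from .graphs import Network

__all__ = [
    "TemporalEventList",
    "SplitHalves",
    "read_event_list",
    "write_event_list",
    "split_half",
    "build_method1",
    "build_method2",
    "generate_synthetic_contacts",
]


@dataclass(frozen=True)
class TemporalEventList:
    """Time-ordered (t, u, v) contact events over nonnegative node ids."""

    events: tuple[tuple[float, int, int], ...]

    def __post_init__(self) -> None:
        prev = None
        for t, u, v in self.events:
            if u == v:
                raise ValueError(f"self-contact ({u}, {u}) at t={t} not allowed")
            if u < 0 or v < 0:
                raise ValueError("node ids must be nonnegative")
            if prev is not None and t < prev:
                raise ValueError("events must be sorted by timestamp")
            prev = t

    def __len__(self) -> int:
        return len(self.events)

    @property
    def nodes(self) -> set[int]:
        return {u for _, u, v in self.events} | {v for _, u, v in self.events}


@dataclass(frozen=True)
class SplitHalves:
    """The two halves of an event list, as node/edge sets over the original
    node universe (0..n_nodes-1)."""

    n_nodes: int
    v1: frozenset[int]
    v2: frozenset[int]
    e1: frozenset[tuple[int, int]]
    e2: frozenset[tuple[int, int]]
    n_events_first: int
    n_events_second: int


def read_event_list(path: str | Path) -> TemporalEventList:
    events: list[tuple[float, int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 't u v', got {line!r}")
            try:
                t, u, v = float(parts[0]), int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable entry {line!r}") from exc
            events.append((t, u, v))
    events.sort(key=lambda e: e[0])
    return TemporalEventList(tuple(events))


def write_event_list(ev: TemporalEventList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# t\tu\tv\n")
        for t, u, v in sorted(ev.events, key=lambda e: e[0]):
            fh.write(f"{t:g}\t{u}\t{v}\n")


def split_half(ev: TemporalEventList) -> SplitHalves:
    """Split at the median event index: the first ceil(M/2) events form the
    first half; events tied with the boundary timestamp stay in the first
    half.  Each half is deduplicated into an unweighted simple graph."""
    m = len(ev)
    if m < 2:
        raise ValueError(f"need at least 2 events to split, got {m}")
    k = ceil(m / 2)
    while k < m and ev.events[k][0] == ev.events[k - 1][0]:
        k += 1
    first, second = ev.events[:k], ev.events[k:]
    n_nodes = max(ev.nodes) + 1

    def edge_set(events):
        return frozenset(
            (min(u, v), max(u, v)) for _, u, v in events
        )

    def node_set(events):
        return frozenset({u for _, u, v in events} | {v for _, u, v in events})

    return SplitHalves(
        n_nodes=n_nodes,
        v1=node_set(first),
        v2=node_set(second),
        e1=edge_set(first),
        e2=edge_set(second),
        n_events_first=len(first),
        n_events_second=len(second),
    )


def _network_from_edges(
    nodes: list[int], edges: frozenset[tuple[int, int]]
) -> tuple[Network, dict[int, int]]:
    mapping = {orig: i for i, orig in enumerate(sorted(nodes))}
    A = np.zeros((len(nodes), len(nodes)))
    for u, v in edges:
        if u in mapping and v in mapping:
            A[mapping[u], mapping[v]] = A[mapping[v], mapping[u]] = 1.0
    return Network(A), mapping


def build_method1(halves: SplitHalves) -> tuple[Network, Network, dict[int, int]]:
    """Restrict both snapshots to the common nodes V1 ∩ V2.

    Nodes are relabeled to 0..|V1∩V2|-1; the original-id -> new-id mapping is
    returned.  Edges with an endpoint outside the intersection are dropped.
    """
    common = sorted(halves.v1 & halves.v2)
    if not common:
        raise ValueError("the two halves share no nodes; method 1 is not applicable")
    g1, mapping = _network_from_edges(common, halves.e1)
    g2, _ = _network_from_edges(common, halves.e2)
    return g1, g2, mapping


def build_method2(halves: SplitHalves) -> tuple[Network, Network]:
    """Keep all nodes of V1 ∪ V2 in both snapshots; a node absent from one
    half is isolated in that snapshot."""
    universe = sorted(halves.v1 | halves.v2)
    g1, _ = _network_from_edges(universe, halves.e1)
    g2, _ = _network_from_edges(universe, halves.e2)
    return g1, g2


def generate_synthetic_contacts(
    n_nodes: int, n_events: int, seed: int, overlap: float = 1.0
) -> TemporalEventList:
    """Synthetic contact sequence whose aggregate graph is connected.

    A random spanning tree over all nodes is embedded in the event stream,
    so the union of the two halves is always connected.  ``overlap`` is the
    fraction of nodes appearing in both halves; the remaining nodes are
    confined to one half each (their snapshot in the other half leaves them
    isolated), exercising both snapshot constructions.  First-half events
    get timestamps in [0, 1), second-half events in [1, 2); with the event
    counts balanced the median-index split recovers the halves exactly.
    """
    if n_nodes < 3:
        raise ValueError(f"need at least 3 nodes, got {n_nodes}")
    if n_events < n_nodes:
        raise ValueError("need at least as many events as nodes")
    if not 0.0 <= overlap <= 1.0:
        raise ValueError(f"overlap must be in [0, 1], got {overlap}")
    rng = np.random.default_rng(seed)

    n_excl = int(round((1.0 - overlap) * n_nodes))
    n_core = n_nodes - n_excl
    if n_core < 2:
        raise ValueError(
            f"overlap={overlap} leaves only {n_core} shared node(s); need >= 2"
        )
    # halves available to each node: core nodes in both, exclusives in one
    order = rng.permutation(n_nodes)
    core = set(order[:n_core].tolist())
    excl1 = set(order[n_core : n_core + (n_excl + 1) // 2].tolist())
    avail = {
        i: (1, 2) if i in core else ((1,) if i in excl1 else (2,)) for i in range(n_nodes)
    }

    # spanning tree: attach each node to an earlier compatible node,
    # balancing tree edges across halves where either half works
    tree_order = [int(i) for i in order]  # core nodes first guarantees anchors
    events_by_half: dict[int, list[tuple[int, int]]] = {1: [], 2: []}
    for pos, u in enumerate(tree_order[1:], start=1):
        candidates = [
            v for v in tree_order[:pos] if set(avail[u]) & set(avail[v])
        ]
        v = int(rng.choice(candidates))
        halves = sorted(set(avail[u]) & set(avail[v]))
        half = halves[0] if len(halves) == 1 else min(
            halves, key=lambda h: len(events_by_half[h])
        )
        events_by_half[half].append((u, v))

    m1_target = ceil(n_events / 2)
    # top up with random compatible contacts
    while len(events_by_half[1]) + len(events_by_half[2]) < n_events:
        need1 = len(events_by_half[1]) < m1_target
        half = 1 if need1 else 2
        pool = [i for i in range(n_nodes) if half in avail[i]]
        u, v = rng.choice(pool, size=2, replace=False)
        events_by_half[half].append((int(u), int(v)))
    if len(events_by_half[1]) > m1_target or len(
        events_by_half[2]
    ) > n_events - m1_target:
        raise ValueError(
            "infeasible parameters: the spanning tree does not fit the event budget"
        )

    events: list[tuple[float, int, int]] = []
    for half, offset in ((1, 0.0), (2, 1.0)):
        ts = np.sort(rng.random(len(events_by_half[half]))) + offset
        events.extend(
            (float(t), u, v) for t, (u, v) in zip(ts, events_by_half[half])
        )
    events.sort(key=lambda e: e[0])
    return TemporalEventList(tuple(events))
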