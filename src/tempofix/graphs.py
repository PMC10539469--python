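"""Static networks that switching networks are built from.

A :class:`Network` is a weighted, undirected, simple graph stored as a dense
symmetric adjacency matrix.  Node ids are 0-based; by convention the hub of a
star graph is node 0.  The module also provides exhaustive enumeration of
connected unlabeled graphs on up to six nodes, seeded random relabeling, the
weighted aggregate (superposition) of two snapshots, and a TSV edge-list
format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Network",
    "SwitchingNetwork",
    "make_star",
    "make_complete",
    "make_complete_bipartite",
    "make_cycle",
    "enumerate_connected_graphs",
    "random_relabel",
    "aggregate",
    "read_edge_list",
    "write_edge_list",
]


@dataclass(frozen=True)
class Network:
    """Undirected weighted network on ``n_nodes`` labeled nodes.

    Parameters
    ----------
    weights
        Symmetric nonnegative matrix with zero diagonal; ``weights[i, j]`` is
        the weight of edge (i, j) and 0 means no edge.
    label
        Free-text identifier used in reports.
    """

    weights: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        A = np.asarray(self.weights, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if A.shape[0] < 1:
            raise ValueError("network needs at least one node")
        if np.any(A < 0):
            raise ValueError("edge weights must be nonnegative")
        if np.any(np.diag(A) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency matrix must be symmetric (undirected)")
        object.__setattr__(self, "weights", A)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def strengths(self) -> np.ndarray:
        """Node strengths w(i) = sum_j A_ij (weighted degrees)."""
        return self.weights.sum(axis=1)

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(sp.csr_matrix(self.weights), directed=False)
        return n_comp == 1

    def degree_sequence(self) -> tuple[int, ...]:
        """Sorted unweighted degree sequence (number of incident edges)."""
        return tuple(sorted(int(d) for d in (self.weights > 0).sum(axis=1)))

    def n_edges(self) -> int:
        return int((self.weights > 0).sum()) // 2


@dataclass(frozen=True)
class SwitchingNetwork:
    """Temporal network alternating between two snapshots.

    Exactly one of ``tau`` (deterministic switching every ``tau`` steps,
    starting on ``g1``) and ``p`` (Markovian switching with per-step
    probability ``p``) must be set.
    """

    g1: Network
    g2: Network
    tau: int | None = None
    p: float | None = None

    def __post_init__(self) -> None:
        if self.g1.n_nodes != self.g2.n_nodes:
            raise ValueError("g1 and g2 must have the same number of nodes")
        if (self.tau is None) == (self.p is None):
            raise ValueError("exactly one of tau (periodic) or p (stochastic) must be set")
        if self.tau is not None and (int(self.tau) != self.tau or self.tau < 1):
            raise ValueError("tau must be a positive integer")
        if self.p is not None and not (0.0 < self.p <= 1.0):
            raise ValueError("p must lie in (0, 1]")

    @property
    def mode(self) -> str:
        return "periodic" if self.tau is not None else "stochastic"


# ---------------------------------------------------------------------------
# standard constructions
# ---------------------------------------------------------------------------

def make_star(n: int) -> Network:
    """Star graph: node 0 is the hub adjacent to all n-1 leaves."""
    if n < 2:
        raise ValueError(f"star graph needs n >= 2, got {n}")
    A = np.zeros((n, n))
    A[0, 1:] = A[1:, 0] = 1.0
    return Network(A, label=f"star({n})")


def make_complete(n: int) -> Network:
    if n < 2:
        raise ValueError(f"complete graph needs n >= 2, got {n}")
    A = np.ones((n, n)) - np.eye(n)
    return Network(A, label=f"complete({n})")


def make_complete_bipartite(n1: int, n2: int) -> Network:
    """Complete bipartite graph K_{n1,n2}; nodes 0..n1-1 form part V1.

    Node 0 doubles as the star hub in star+bipartite switching networks.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError(f"bipartite parts must be nonempty, got ({n1}, {n2})")
    n = n1 + n2
    A = np.zeros((n, n))
    A[:n1, n1:] = 1.0
    A[n1:, :n1] = 1.0
    return Network(A, label=f"K({n1},{n2})")


def make_cycle(n: int) -> Network:
    if n < 3:
        raise ValueError(f"cycle needs n >= 3, got {n}")
    A = np.zeros((n, n))
    idx = np.arange(n)
    A[idx, (idx + 1) % n] = 1.0
    A[(idx + 1) % n, idx] = 1.0
    return Network(A, label=f"cycle({n})")


# ---------------------------------------------------------------------------
# enumeration of connected unlabeled graphs (n <= 6)
# ---------------------------------------------------------------------------

def _edge_pairs(n: int) -> list[tuple[int, int]]:
    return list(combinations(range(n), 2))


def _mask_to_network(mask: int, n: int, pairs: list[tuple[int, int]]) -> Network:
    A = np.zeros((n, n))
    for e, (u, v) in enumerate(pairs):
        if mask >> e & 1:
            A[u, v] = A[v, u] = 1.0
    return Network(A, label=f"g{n}-{mask:05x}")


def _connected_mask(mask: int, n: int, pairs: list[tuple[int, int]]) -> bool:
    # BFS over node bitmasks
    nbr = [0] * n
    for e, (u, v) in enumerate(pairs):
        if mask >> e & 1:
            nbr[u] |= 1 << v
            nbr[v] |= 1 << u
    seen = 1
    frontier = 1
    while frontier:
        nxt = 0
        m = frontier
        while m:
            i = (m & -m).bit_length() - 1
            m &= m - 1
            nxt |= nbr[i]
        frontier = nxt & ~seen
        seen |= nxt
    return seen == (1 << n) - 1


def canonical_form(g: Network) -> int:
    """Lexicographically minimal adjacency bitstring over all node permutations.

    Only defined for unweighted graphs; used to deduplicate isomorphism
    classes at n <= 6.
    """
    n = g.n_nodes
    pairs = _edge_pairs(n)
    eidx = {p: e for e, p in enumerate(pairs)}
    bits = [int(g.weights[u, v] > 0) for (u, v) in pairs]
    best = None
    for perm in permutations(range(n)):
        val = 0
        for e, (u, v) in enumerate(pairs):
            if bits[e]:
                pu, pv = perm[u], perm[v]
                val |= 1 << eidx[(pu, pv) if pu < pv else (pv, pu)]
        if best is None or val < best:
            best = val
    return best


def enumerate_connected_graphs(n: int) -> list[Network]:
    """One canonical representative per isomorphism class of connected
    unweighted graphs on ``n`` nodes, in sorted canonical-form order.

    Exhausts all 2^(n(n-1)/2) labeled graphs, so it refuses n > 6.
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    if n > 6:
        raise ValueError(
            f"exhaustive enumeration is limited to n <= 6 (got n={n}); "
            "the labeled-graph space grows as 2^(n(n-1)/2)"
        )
    pairs = _edge_pairs(n)
    n_edges = len(pairs)
    conn = np.array(
        [m for m in range(1 << n_edges) if _connected_mask(m, n, pairs)],
        dtype=np.int64,
    )
    # bit matrix (n_graphs, n_edges)
    bits = (conn[:, None] >> np.arange(n_edges)[None, :]) & 1
    eidx = {p: e for e, p in enumerate(pairs)}
    best = np.full(conn.shape, np.iinfo(np.int64).max, dtype=np.int64)
    for perm in permutations(range(n)):
        shift = np.empty(n_edges, dtype=np.int64)
        for e, (u, v) in enumerate(pairs):
            pu, pv = perm[u], perm[v]
            shift[e] = eidx[(pu, pv) if pu < pv else (pv, pu)]
        vals = bits @ (np.int64(1) << shift)
        np.minimum(best, vals, out=best)
    canon = np.unique(best)
    return [_mask_to_network(int(m), n, pairs) for m in canon]


# ---------------------------------------------------------------------------
# relabeling and aggregation
# ---------------------------------------------------------------------------

def random_relabel(g: Network, seed: int | np.random.Generator) -> Network:
    """Conjugate the adjacency by a uniformly random node permutation.

    The permutation is drawn with ``numpy.random.default_rng(seed)``; passing
    the same seed reproduces the same relabeling.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(g.n_nodes)
    A = g.weights[np.ix_(perm, perm)]
    return Network(A, label=f"{g.label}~relabel")


def aggregate(g1: Network, g2: Network) -> Network:
    """Weighted superposition A1 + A2 of two snapshots (time-average x2)."""
    if g1.n_nodes != g2.n_nodes:
        raise ValueError(
            f"cannot aggregate networks of different sizes ({g1.n_nodes} vs {g2.n_nodes})"
        )
    return Network(g1.weights + g2.weights, label=f"aggregate({g1.label},{g2.label})")


# ---------------------------------------------------------------------------
# edge-list I/O (TSV: "u <tab> v [<tab> weight]", '#' comments)
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> Network:
    edges: list[tuple[int, int, float]] = []
    max_node = -1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 'u v [weight]', got {line!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
                w = float(parts[2]) if len(parts) == 3 else 1.0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable entry: {line!r}") from exc
            if u < 0 or v < 0:
                raise ValueError(f"{path}:{lineno}: node ids must be nonnegative")
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop ({u}, {v}) not allowed")
            if w < 0:
                raise ValueError(f"{path}:{lineno}: negative weight {w}")
            edges.append((u, v, w))
            max_node = max(max_node, u, v)
    if max_node < 0:
        raise ValueError(f"{path}: no edges found")
    A = np.zeros((max_node + 1, max_node + 1))
    for u, v, w in edges:
        A[u, v] = A[v, u] = w
    return Network(A, label=str(path))


def write_edge_list(g: Network, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_nodes={g.n_nodes}\n")
        for u in range(g.n_nodes):
            for v in range(u + 1, g.n_nodes):
                w = g.weights[u, v]
                if w != 0:
                    fh.write(f"{u}\t{v}\t{w:g}\n")
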