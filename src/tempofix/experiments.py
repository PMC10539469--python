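"""Exhaustive six-node experiments and symmetric-family scans.

The six-node sweeps classify every ordered pair of the 112 connected
unlabeled six-node graphs as a switching network, with the second snapshot
relabeled by one uniformly random permutation per pair (drawn from a per-pair
substream of the sweep seed).  The computation exploits two facts to stay
fast: the per-graph transition matrices (and their tau-th powers) depend only
on the 112 canonical graphs and the fitness grid, so they are precomputed
once; and relabeling a graph conjugates its chain by the induced permutation
of state bitmasks, so the relabeled matrix is a fancy-indexed view of the
precomputed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations as _it_permutations
from typing import Any, Iterable, Sequence

import numpy as np

from .chain import build_transition_matrix
from .classify import (
    DEFAULT_TOL,
    R_GRID,
    R_LARGE_PROBES,
    Classification,
    classify_values,
)
from .graphs import Network, enumerate_connected_graphs
from .reduced import (
    fixation_switching_reduced,
    star_bipartite_chains,
    star_complete_chains,
)
from .solvers import moran_probability

__all__ = [
    "SweepResult",
    "census_static_sixnode",
    "verdict_counts",
    "sweep_pairs",
    "sweep_sixnode_periodic",
    "sweep_sixnode_stochastic",
    "scan_star_complete",
    "scan_star_bipartite",
]


@dataclass(frozen=True)
class SweepResult:
    """Tally of verdicts over all ordered snapshot pairs of a sweep."""

    parameter: dict[str, Any]
    counts: dict[str, int]
    records: list[dict[str, Any]]
    seed: int | None

    @property
    def n_pairs(self) -> int:
        return sum(self.counts.values())

    def fraction(self, verdict: str) -> float:
        return self.counts.get(verdict, 0) / self.n_pairs


def state_permutation(perm: Sequence[int]) -> np.ndarray:
    """Permutation of state bitmasks induced by a node permutation.

    If B = A[perm][:, perm] (new node i is old node perm[i]), then the chain
    of B is the chain of A conjugated by phi, where bit i of the new state is
    bit perm[i] of the old state.
    """
    n = len(perm)
    phi = np.zeros(1 << n, dtype=np.int64)
    for i, p in enumerate(perm):
        bit = (np.arange(1 << n) >> i) & 1
        phi |= bit.astype(np.int64) << int(p)
    return phi


def _matrix_stack(g: Network, r_grid: Sequence[float], power: int = 1) -> np.ndarray:
    """Stack of dense transition matrices (optionally tau-th powers), one
    per grid fitness."""
    mats = []
    for r in r_grid:
        T = build_transition_matrix(g, r).dense()
        mats.append(np.linalg.matrix_power(T, power) if power != 1 else T)
    return np.stack(mats)


def _batched_rho(M: np.ndarray, n_nodes: int) -> np.ndarray:
    """Uniform-initialization fixation probability for each matrix in a
    stack of 2^N-state switching propagators."""
    S = M.shape[-1]
    t = np.arange(1, S - 1)
    A = np.eye(S - 2)[None] - M[:, t[:, None], t[None, :]]
    b = M[:, t, S - 1]
    x = np.linalg.solve(A, b[..., None])[..., 0]
    sm = (np.int64(1) << np.arange(n_nodes)) - 1  # positions in transient block
    return x[:, sm].mean(axis=1)


def _batched_rho_stochastic(
    T1: np.ndarray, T2: np.ndarray, p: float, n_nodes: int, process: str = "flip"
) -> np.ndarray:
    """Fixation probability under stochastic switching for stacks of
    snapshot chains; averages over the two equally likely initial
    snapshots.  ``process`` is "flip" (Markovian switching) or "redraw"
    (independent per-step snapshot draw, G1 with probability p)."""
    n_r, S, _ = T1.shape
    M = np.zeros((n_r, 2 * S, 2 * S))
    if process == "flip":
        M[:, :S, :S] = (1.0 - p) * T1
        M[:, :S, S:] = p * T1
        M[:, S:, :S] = p * T2
        M[:, S:, S:] = (1.0 - p) * T2
    elif process == "redraw":
        M[:, :S, :S] = p * T1
        M[:, :S, S:] = (1.0 - p) * T1
        M[:, S:, :S] = p * T2
        M[:, S:, S:] = (1.0 - p) * T2
    else:
        raise ValueError(f"unknown snapshot process {process!r}")
    boundary = np.array([0, S - 1, S, 2 * S - 1])
    t = np.setdiff1d(np.arange(2 * S), boundary)
    A = np.eye(t.size)[None] - M[:, t[:, None], t[None, :]]
    b = M[:, t[:, None], boundary[None, [1, 3]]].sum(axis=2)
    x = np.linalg.solve(A, b[..., None])[..., 0]
    pos = {s: i for i, s in enumerate(t)}
    sm = np.int64(1) << np.arange(n_nodes)
    cols = np.array([pos[s] for s in sm] + [pos[S + s] for s in sm])
    return x[:, cols].mean(axis=1)


# ---------------------------------------------------------------------------
# static census
# ---------------------------------------------------------------------------

def census_static_sixnode(
    r_grid: Sequence[float] = R_GRID + R_LARGE_PROBES, tol: float = DEFAULT_TOL
) -> list[Classification]:
    """Exact amplifier/suppressor classification of all 112 connected
    six-node graphs as static networks.

    Static censuses use the classical all-r notion of amplification, so the
    nine-point grid is augmented with large-r probes by default: three
    six-node graphs lie below the Moran curve on the whole nine-point grid
    yet re-cross it between r = 2 and r = 6, which makes them "neither"
    rather than suppressors.
    """
    out = []
    for g in enumerate_connected_graphs(6):
        T = _matrix_stack(g, r_grid)
        rho = _batched_rho(T, g.n_nodes)
        out.append(classify_values(dict(zip(r_grid, rho)), g.n_nodes, tol))
    return out


def verdict_counts(classifications: Iterable[Classification]) -> dict[str, int]:
    counts = {"amplifier": 0, "suppressor": 0, "isothermal": 0, "neither": 0}
    for c in classifications:
        counts[c.verdict] += 1
    return counts


# ---------------------------------------------------------------------------
# ordered-pair sweeps
# ---------------------------------------------------------------------------

def sweep_pairs(
    graphs: Sequence[Network],
    *,
    tau: int | None = None,
    p: float | None = None,
    seed: int = 0,
    r_grid: Sequence[float] = R_GRID,
    tol: float = DEFAULT_TOL,
    process: str = "flip",
    progress: bool = False,
) -> SweepResult:
    """Classify every ordered pair (G1, G2) of distinct graphs as a
    switching network, relabeling G2 by one seeded random permutation per
    pair.

    ``tau`` selects periodic switching (start on G1); ``p`` selects
    stochastic switching with a uniformly random initial snapshot and the
    given per-step snapshot ``process`` ("flip" or "redraw").
    """
    if (tau is None) == (p is None):
        raise ValueError("set exactly one of tau (periodic) or p (stochastic)")
    n = graphs[0].n_nodes
    if any(g.n_nodes != n for g in graphs):
        raise ValueError("all graphs in a sweep must have the same node count")
    power = tau if tau is not None else 1
    stacks = [_matrix_stack(g, r_grid, power=power) for g in graphs]

    n_graphs = len(graphs)
    pairs = [(a, b) for a in range(n_graphs) for b in range(n_graphs) if a != b]
    streams = np.random.SeedSequence(seed).spawn(len(pairs))
    iterator = zip(pairs, streams)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(list(iterator), desc="sweep")

    counts = {"amplifier": 0, "suppressor": 0, "isothermal": 0, "neither": 0}
    records: list[dict[str, Any]] = []
    for (a, b), stream in iterator:
        rng = np.random.default_rng(stream)
        perm = rng.permutation(n)
        phi = state_permutation(perm)
        P2 = stacks[b][:, phi[:, None], phi[None, :]]
        if tau is not None:
            rho = _batched_rho(stacks[a] @ P2, n)
        else:
            rho = _batched_rho_stochastic(stacks[a], P2, p, n, process)
        cls = classify_values(dict(zip(r_grid, rho)), n, tol)
        counts[cls.verdict] += 1
        records.append(
            {
                "g1": graphs[a].label,
                "g2": graphs[b].label,
                "permutation": perm.tolist(),
                "verdict": cls.verdict,
                **{f"rho_r{r}": cls.rho_by_r[r] for r in r_grid},
            }
        )
    parameter = {"tau": tau} if tau is not None else {"p": p, "process": process}
    return SweepResult(parameter=parameter, counts=counts, records=records, seed=seed)


def sweep_sixnode_periodic(
    tau: int, seed: int, *, progress: bool = False
) -> SweepResult:
    """All 112*111 ordered six-node pairs under periodic switching."""
    if tau < 1:
        raise ValueError(f"tau must be >= 1, got {tau}")
    return sweep_pairs(
        enumerate_connected_graphs(6), tau=tau, seed=seed, progress=progress
    )


def sweep_sixnode_stochastic(
    p: float, seed: int, *, process: str = "flip", progress: bool = False
) -> SweepResult:
    """All 112*111 ordered six-node pairs under stochastic switching with
    random initialization (uniform initial snapshot).

    ``process="flip"`` is the Markovian model (snapshot flips with
    probability p each step); ``process="redraw"`` draws the next snapshot
    independently each step (G1 with probability p).  The two coincide at
    p = 0.5.
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must be in (0, 1), got {p}")
    return sweep_pairs(
        enumerate_connected_graphs(6), p=p, seed=seed, process=process,
        progress=progress,
    )


# ---------------------------------------------------------------------------
# symmetric-family scans
# ---------------------------------------------------------------------------

def scan_star_complete(
    n_min: int = 3,
    n_max: int = 10,
    tau: int = 1,
    r_pair: tuple[float, float] = (0.9, 1.1),
) -> list[dict[str, Any]]:
    """Sign pattern of rho - Moran at a deleterious/advantageous fitness
    pair for the star+complete switching network, per population size N."""
    if n_min < 3:
        raise ValueError("star+complete reduction needs N >= 3")
    out = []
    r_lo, r_hi = r_pair
    for n in range(n_min, n_max + 1):
        diffs = {}
        for r in (r_lo, r_hi):
            rc = star_complete_chains(n, r)
            diffs[r] = fixation_switching_reduced(rc, tau).rho - moran_probability(r, n)
        if diffs[r_lo] > 0 and diffs[r_hi] < 0:
            pattern = "suppressor"
        elif diffs[r_lo] < 0 and diffs[r_hi] > 0:
            pattern = "amplifier"
        else:
            pattern = "neither"
        out.append({"n": n, "tau": tau, "pattern": pattern, "diffs": diffs})
    return out


def scan_star_bipartite(
    n1_range: Iterable[int] = range(2, 11),
    n2_range: Iterable[int] = range(2, 11),
    tau: int = 1,
    tol: float = DEFAULT_TOL,
) -> dict[tuple[int, int], Classification]:
    """Full nine-grid classification of the star+K_{N1,N2} switching network
    over a grid of part sizes."""
    out: dict[tuple[int, int], Classification] = {}
    for n1 in n1_range:
        for n2 in n2_range:
            n = n1 + n2
            rho_by_r = {}
            for r in R_GRID:
                rc = star_bipartite_chains(n1, n2, r)
                rho_by_r[r] = fixation_switching_reduced(rc, tau).rho
            out[(n1, n2)] = classify_values(rho_by_r, n, tol)
    return out
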