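"""Symmetry-reduced (lumped) chains for highly symmetric switching networks.

For the star+complete and star+complete-bipartite families the leaves of the
star are structurally interchangeable in both snapshots, so the 2^N-state
chain lumps exactly onto orbit states: (hub occupancy i, leaf mutant count j)
for star+complete (2N states), and (i, j, k) with j mutants among the N1-1
star leaves inside part V1 and k mutants among the N2 nodes of part V2 for
star+K_{N1,N2} (2 N1 (N2+1) states).  This turns the 2^N - 2 fixation
equations into 2N - 2 (resp. 2 N1 (N2+1) - 2), making N in the tens exact.

``lump_chain`` performs generic exact lumping of a full chain under a node
partition, verifying the lumpability condition entrywise; it is the
independent cross-check for the closed-form constructions below.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Any

import numpy as np

from .chain import StateChain
from .solvers import FixationResult, solve_fixed_point

__all__ = [
    "ReducedChainSC",
    "ReducedChainSB",
    "star_complete_chains",
    "star_bipartite_chains",
    "lump_chain",
    "fixation_switching_reduced",
    "fixation_static_reduced",
]


@dataclass(frozen=True)
class ReducedChainSC:
    """Lumped chains for the star (T1) / complete graph (T2) pair.

    States (i, j): i in {0, 1} is the hub occupancy, j in 0..N-1 the number
    of mutant leaves; index = i*N + j.  (0, 0) and (1, N-1) are absorbing.
    """

    n: int
    r: float
    T1: np.ndarray
    T2: np.ndarray

    def index(self, i: int, j: int) -> int:
        return i * self.n + j

    @property
    def zero_index(self) -> int:
        return self.index(0, 0)

    @property
    def one_index(self) -> int:
        return self.index(1, self.n - 1)

    @property
    def init_weights(self) -> np.ndarray:
        """Uniform single-mutant initialization mapped to orbit states:
        the mutant is the hub with probability 1/N, a leaf with (N-1)/N."""
        w = np.zeros(2 * self.n)
        w[self.index(1, 0)] = 1.0 / self.n
        w[self.index(0, 1)] = (self.n - 1) / self.n
        return w


@dataclass(frozen=True)
class ReducedChainSB:
    """Lumped chains for the star (T1) / complete bipartite K_{N1,N2} (T2)
    pair, the hub being one of the N1 nodes of part V1.

    States (i, j, k): hub occupancy, mutants among the N1-1 leaves in V1,
    mutants among the N2 nodes of V2; index = i*N1*(N2+1) + j*(N2+1) + k.
    (0, 0, 0) and (1, N1-1, N2) are absorbing.
    """

    n1: int
    n2: int
    r: float
    T1: np.ndarray
    T2: np.ndarray

    @property
    def n(self) -> int:
        return self.n1 + self.n2

    def index(self, i: int, j: int, k: int) -> int:
        return (i * self.n1 + j) * (self.n2 + 1) + k

    @property
    def zero_index(self) -> int:
        return self.index(0, 0, 0)

    @property
    def one_index(self) -> int:
        return self.index(1, self.n1 - 1, self.n2)

    @property
    def init_weights(self) -> np.ndarray:
        w = np.zeros(2 * self.n1 * (self.n2 + 1))
        w[self.index(1, 0, 0)] = 1.0 / self.n
        w[self.index(0, 1, 0)] = (self.n1 - 1) / self.n
        w[self.index(0, 0, 1)] = self.n2 / self.n
        return w


def star_complete_chains(n: int, r: float) -> ReducedChainSC:
    """Closed-form lumped transition matrices for the star+complete pair.

    In the star only the hub can convert leaves and only leaves can convert
    the hub, so moves (1,j)->(1,j-1) and (0,j)->(0,j+1) have probability 0
    in T1; both occur in T2 (complete graph).
    """
    if n < 3:
        raise ValueError(f"star+complete reduction needs n >= 3, got {n}")
    if r <= 0:
        raise ValueError(f"fitness r must be positive, got {r}")
    S = 2 * n
    T1 = np.zeros((S, S))
    T2 = np.zeros((S, S))
    idx = lambda i, j: i * n + j  # noqa: E731
    L = n - 1  # number of leaves

    for j in range(n):
        # --- hub resident, j mutant leaves ---------------------------------
        if j >= 1:  # (0, 0) is absorbing
            C1 = r * j + n - j
            # star: a mutant leaf reproduces; its only neighbor is the hub
            T1[idx(0, j), idx(1, j)] = r * j / C1
            # star: the hub reproduces into a mutant leaf
            T1[idx(0, j), idx(0, j - 1)] = (1.0 / C1) * (j / L)
            # complete graph: same events plus leaf-to-leaf replacement
            T2[idx(0, j), idx(1, j)] = (r * j / C1) * (1.0 / L)
            T2[idx(0, j), idx(0, j - 1)] = ((n - j) / C1) * (j / L)
            if j <= n - 2:
                T2[idx(0, j), idx(0, j + 1)] = (r * j / C1) * ((L - j) / L)
        # --- hub mutant, j mutant leaves -----------------------------------
        if j <= n - 2:  # (1, n-1) is absorbing
            C2 = r * (j + 1) + n - (j + 1)
            T1[idx(1, j), idx(1, j + 1)] = (r / C2) * ((L - j) / L)
            T1[idx(1, j), idx(0, j)] = (L - j) / C2
            T2[idx(1, j), idx(1, j + 1)] = (r * (j + 1) / C2) * ((L - j) / L)
            T2[idx(1, j), idx(0, j)] = ((L - j) / C2) * (1.0 / L)
            if j >= 1:
                T2[idx(1, j), idx(1, j - 1)] = ((L - j) / C2) * (j / L)

    for T in (T1, T2):
        np.fill_diagonal(T, np.diag(T) + (1.0 - T.sum(axis=1)))
    return ReducedChainSC(n=n, r=r, T1=T1, T2=T2)


def star_bipartite_chains(n1: int, n2: int, r: float) -> ReducedChainSB:
    """Closed-form lumped matrices for the star+K_{N1,N2} pair.

    T1 expresses the star on (i, j, k): the j+k leaf mutants all behave as
    star leaves.  In T2 every V1 node reproduces into a uniformly chosen V2
    node and vice versa, with parents chosen proportional to fitness.
    """
    if n1 < 2 or n2 < 1:
        raise ValueError(f"need n1 >= 2 and n2 >= 1, got ({n1}, {n2})")
    if r <= 0:
        raise ValueError(f"fitness r must be positive, got {r}")
    n = n1 + n2
    S = 2 * n1 * (n2 + 1)
    T1 = np.zeros((S, S))
    T2 = np.zeros((S, S))
    idx = lambda i, j, k: (i * n1 + j) * (n2 + 1) + k  # noqa: E731
    L = n - 1  # star leaves

    for i in (0, 1):
        for j in range(n1):
            for k in range(n2 + 1):
                if i == 0 and j == 0 and k == 0:
                    continue  # resident fixation, absorbing
                if i == 1 and j == n1 - 1 and k == n2:
                    continue  # mutant fixation, absorbing
                m = i + j + k
                D = r * m + n - m
                s = idx(i, j, k)
                # ---- T1: star ------------------------------------------
                if i == 0:
                    if j + k >= 1:
                        T1[s, idx(1, j, k)] = r * (j + k) / D
                    if j >= 1:
                        T1[s, idx(0, j - 1, k)] = (1.0 / D) * (j / L)
                    if k >= 1:
                        T1[s, idx(0, j, k - 1)] = (1.0 / D) * (k / L)
                else:
                    if j <= n1 - 2:
                        T1[s, idx(1, j + 1, k)] = (r / D) * ((n1 - 1 - j) / L)
                    if k <= n2 - 1:
                        T1[s, idx(1, j, k + 1)] = (r / D) * ((n2 - k) / L)
                    n_res_leaves = (n1 - 1 - j) + (n2 - k)
                    if n_res_leaves:
                        T1[s, idx(0, j, k)] = n_res_leaves / D
                # ---- T2: complete bipartite ----------------------------
                mut_v1 = i + j
                res_v1 = n1 - mut_v1
                if mut_v1 and k < n2:  # mutant in V1 reproduces into V2
                    T2[s, idx(i, j, k + 1)] = (r * mut_v1 / D) * ((n2 - k) / n2)
                if res_v1 and k:  # resident in V1 reproduces into V2
                    T2[s, idx(i, j, k - 1)] = (res_v1 / D) * (k / n2)
                if k:  # mutant in V2 reproduces into V1
                    if i == 0:
                        T2[s, idx(1, j, k)] = (r * k / D) * (1.0 / n1)
                    if j <= n1 - 2:
                        T2[s, idx(i, j + 1, k)] = (r * k / D) * ((n1 - 1 - j) / n1)
                if k < n2:  # resident in V2 reproduces into V1
                    if i == 1:
                        T2[s, idx(0, j, k)] = ((n2 - k) / D) * (1.0 / n1)
                    if j >= 1:
                        T2[s, idx(i, j - 1, k)] = ((n2 - k) / D) * (j / n1)

    for T in (T1, T2):
        np.fill_diagonal(T, np.diag(T) + (1.0 - T.sum(axis=1)))
    return ReducedChainSB(n1=n1, n2=n2, r=r, T1=T1, T2=T2)


# ---------------------------------------------------------------------------
# generic exact lumping (cross-check route)
# ---------------------------------------------------------------------------

def lump_chain(
    chain: StateChain, node_classes: list[int] | np.ndarray, *, tol: float = 1e-12
) -> tuple[np.ndarray, list[tuple[int, ...]], np.ndarray]:
    """Exactly lump a full 2^N chain under a partition of the nodes.

    ``node_classes[i]`` is the orbit class of node i; an orbit state is the
    tuple of mutant counts per class.  Every micro state in an orbit must
    have identical summed transition probability into every target orbit
    (checked to ``tol``); otherwise the partition is not lumpable and a
    ``ValueError`` is raised.

    Returns ``(T_lumped, orbit_states, micro_to_macro)``.
    """
    classes = np.asarray(node_classes)
    n = chain.n_nodes
    if classes.shape != (n,):
        raise ValueError("node_classes must assign a class to every node")
    n_classes = classes.max() + 1
    n_states = chain.n_states
    states = np.arange(n_states, dtype=np.int64)
    bits = (states[:, None] >> np.arange(n)[None, :]) & 1
    counts = np.stack(
        [bits[:, classes == c].sum(axis=1) for c in range(n_classes)], axis=1
    )
    orbit_of: dict[tuple[int, ...], int] = {}
    micro_to_macro = np.empty(n_states, dtype=np.int64)
    orbit_states: list[tuple[int, ...]] = []
    for s in range(n_states):
        key = tuple(int(c) for c in counts[s])
        if key not in orbit_of:
            orbit_of[key] = len(orbit_states)
            orbit_states.append(key)
        micro_to_macro[s] = orbit_of[key]
    n_orbits = len(orbit_states)

    T = chain.dense()
    # aggregate columns by target orbit
    agg = np.zeros((n_states, n_orbits))
    np.add.at(agg.T, micro_to_macro, T.T)
    T_lumped = np.zeros((n_orbits, n_orbits))
    for o in range(n_orbits):
        members = np.flatnonzero(micro_to_macro == o)
        rows = agg[members]
        spread = np.abs(rows - rows[0]).max() if len(members) > 1 else 0.0
        if spread > tol:
            raise ValueError(
                f"partition is not lumpable: orbit {orbit_states[o]} has "
                f"inconsistent outgoing probabilities (spread {spread:.3e})"
            )
        T_lumped[o] = rows[0]
    return T_lumped, orbit_states, micro_to_macro


# ---------------------------------------------------------------------------
# fixation on reduced chains
# ---------------------------------------------------------------------------

def fixation_switching_reduced(
    rc: ReducedChainSC | ReducedChainSB, tau: int
) -> FixationResult:
    """Periodic-switching fixation probabilities on a lumped chain
    (dynamics start on the star snapshot T1)."""
    if tau < 1 or int(tau) != tau:
        raise ValueError(f"tau must be a positive integer, got {tau}")
    M = np.linalg.matrix_power(rc.T1, tau) @ np.linalg.matrix_power(rc.T2, tau)
    x = solve_fixed_point(M, np.array([rc.zero_index]), np.array([rc.one_index]))
    rho = float(rc.init_weights @ x)
    return FixationResult(x, rho, {"mode": "periodic-reduced", "tau": tau, "r": rc.r})


def fixation_static_reduced(
    rc: ReducedChainSC | ReducedChainSB, which: int = 1
) -> FixationResult:
    """Static fixation probabilities under T1 (which=1) or T2 (which=2)."""
    if which not in (1, 2):
        raise ValueError("which must be 1 or 2")
    M = rc.T1 if which == 1 else rc.T2
    x = solve_fixed_point(M, np.array([rc.zero_index]), np.array([rc.one_index]))
    rho = float(rc.init_weights @ x)
    return FixationResult(x, rho, {"mode": "static-reduced", "which": which, "r": rc.r})
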