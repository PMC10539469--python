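"""Exact fixation probabilities for static and switching dynamics.

All solvers reduce to the same linear-algebra step: the fixation-probability
vector is the unique fixed point ``x = M x`` of a row-stochastic matrix M with
the all-resident states pinned to 0 and the all-mutant states pinned to 1.
Restricting to transient states turns this into the nonsingular system
``(I - M_tt) x_t = M_t,one . 1`` which is solved directly.

For periodic switching with interval tau the relevant matrix is
``(T1)^tau (T2)^tau`` (dynamics start on G1); for Markovian switching with
per-step probability p it is the 2*2^N block matrix coupling the two
snapshots; for a mutant arising at a uniformly random time the two anchor
fixed points are propagated backwards through a period and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .chain import StateChain, build_transition_matrix
from .graphs import Network

__all__ = [
    "FixationResult",
    "moran_probability",
    "solve_fixed_point",
    "fixation_static",
    "fixation_switching",
    "fixation_random_init",
    "fixation_stochastic_switching",
]


def moran_probability(r: float, n: int) -> float:
    """Fixation probability of a single mutant in the Moran process,
    (1 - 1/r) / (1 - 1/r^n); the r -> 1 limit is 1/n."""
    if n < 2:
        raise ValueError(f"population size must be at least 2, got {n}")
    if r <= 0:
        raise ValueError(f"fitness r must be positive, got {r}")
    if r == 1.0:
        return 1.0 / n
    return (1.0 - 1.0 / r) / (1.0 - r ** (-n))


@dataclass(frozen=True)
class FixationResult:
    """Per-initial-state fixation probabilities and their uniform summary.

    ``x_star`` has one entry per chain state (2^N for static/periodic
    dynamics, 2*2^N for stochastic switching where the initial snapshot is
    part of the state).  ``rho`` averages ``x_star`` over the single-mutant
    initial states (and over the two initial snapshots in stochastic mode).
    """

    x_star: np.ndarray
    rho: float
    meta: dict[str, Any] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """One row per initial state plus a summary row for rho."""
        df = pd.DataFrame(
            {"state": np.arange(len(self.x_star)), "fixation_probability": self.x_star}
        )
        summary = pd.DataFrame({"state": ["rho"], "fixation_probability": [self.rho]})
        return pd.concat([df, summary], ignore_index=True)


def solve_fixed_point(
    M: np.ndarray, zero_states: np.ndarray, one_states: np.ndarray
) -> np.ndarray:
    """Solve x = M x with x[zero_states] = 0 and x[one_states] = 1.

    M must be row-stochastic with the boundary states closed under M (no
    probability flowing from boundary to transient states).
    """
    n = M.shape[0]
    boundary = np.zeros(n, dtype=bool)
    boundary[zero_states] = True
    boundary[one_states] = True
    t = ~boundary
    A = np.eye(t.sum()) - M[np.ix_(t, t)]
    b = M[np.ix_(t, np.atleast_1d(one_states))].sum(axis=1)
    try:
        x_t = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular fixation system; the (aggregate) network is likely disconnected"
        ) from exc
    x = np.zeros(n)
    x[one_states] = 1.0
    x[t] = x_t
    return x


def _rho_single_mutant(x: np.ndarray, n_nodes: int) -> float:
    idx = np.int64(1) << np.arange(n_nodes)
    return float(x[idx].mean())


def fixation_static(chain: StateChain) -> FixationResult:
    """Fixation probabilities on a single static network."""
    M = chain.dense()
    x = solve_fixed_point(
        M, np.array([0]), np.array([chain.full_state])
    )
    rho = _rho_single_mutant(x, chain.n_nodes)
    return FixationResult(x, rho, {"mode": "static", "r": chain.r})


def _pair_chains(g1: Network, g2: Network, r: float) -> tuple[np.ndarray, np.ndarray, int]:
    if g1.n_nodes != g2.n_nodes:
        raise ValueError(
            f"snapshots must share the node set ({g1.n_nodes} vs {g2.n_nodes} nodes)"
        )
    T1 = build_transition_matrix(g1, r).dense()
    T2 = build_transition_matrix(g2, r).dense()
    return T1, T2, g1.n_nodes


def fixation_switching(g1: Network, g2: Network, tau: int, r: float) -> FixationResult:
    """Periodic switching (G1, G2, tau): dynamics start on G1 and the
    snapshots alternate every tau steps; x* solves x = (T1)^tau (T2)^tau x."""
    if tau < 1 or int(tau) != tau:
        raise ValueError(f"tau must be a positive integer, got {tau}")
    T1, T2, n = _pair_chains(g1, g2, r)
    M = np.linalg.matrix_power(T1, tau) @ np.linalg.matrix_power(T2, tau)
    x = solve_fixed_point(M, np.array([0]), np.array([M.shape[0] - 1]))
    rho = _rho_single_mutant(x, n)
    return FixationResult(x, rho, {"mode": "periodic", "tau": tau, "r": r})


def fixation_random_init(g1: Network, g2: Network, tau: int, r: float) -> FixationResult:
    """Periodic switching with the initial mutant arising at a uniformly
    random time within the 2*tau-step period.

    The two anchor fixed points x*(tau-1) and x*(2*tau-1) solve
    ``x = T1 (T2)^tau (T1)^(tau-1) x`` and ``x = T2 (T1)^tau (T2)^(tau-1) x``;
    propagating them backwards with powers of T1 and T2 and averaging over
    the 2*tau possible arrival times yields the time-averaged vector.
    """
    if tau < 1 or int(tau) != tau:
        raise ValueError(f"tau must be a positive integer, got {tau}")
    T1, T2, n = _pair_chains(g1, g2, r)
    P1 = np.linalg.matrix_power(T1, tau)
    P2 = np.linalg.matrix_power(T2, tau)
    S = T1.shape[0]
    bounds = (np.array([0]), np.array([S - 1]))
    M1 = T1 @ P2 @ np.linalg.matrix_power(T1, tau - 1)
    M2 = T2 @ P1 @ np.linalg.matrix_power(T2, tau - 1)
    x1 = solve_fixed_point(M1, *bounds)  # x*(tau - 1)
    x2 = solve_fixed_point(M2, *bounds)  # x*(2*tau - 1)
    acc = np.zeros(S)
    v1, v2 = x1.copy(), x2.copy()
    for k in range(tau):  # sum_{k=0}^{tau-1} T^k x
        acc += v1 + v2
        if k < tau - 1:
            v1 = T1 @ v1
            v2 = T2 @ v2
    x = acc / (2 * tau)
    rho = _rho_single_mutant(x, n)
    return FixationResult(x, rho, {"mode": "random_init", "tau": tau, "r": r})


def stochastic_block_matrix(
    T1: np.ndarray, T2: np.ndarray, p: float, process: str = "flip"
) -> np.ndarray:
    """Block transition matrix over (population state, active snapshot).

    From (s, G_i) the population moves by T^(i); the next snapshot is then
    chosen by the ``process``:

    - ``"flip"``: Markovian switching — the snapshot flips with probability
      p, so dwell times are geometric with mean 1/p.
    - ``"redraw"``: the next snapshot is drawn independently each step, G1
      with probability p and G2 with probability 1-p, regardless of the
      current snapshot.
    """
    S = T1.shape[0]
    M = np.empty((2 * S, 2 * S))
    if process == "flip":
        M[:S, :S] = (1.0 - p) * T1
        M[:S, S:] = p * T1
        M[S:, :S] = p * T2
        M[S:, S:] = (1.0 - p) * T2
    elif process == "redraw":
        M[:S, :S] = p * T1
        M[:S, S:] = (1.0 - p) * T1
        M[S:, :S] = p * T2
        M[S:, S:] = (1.0 - p) * T2
    else:
        raise ValueError(f"unknown snapshot process {process!r}")
    return M


def fixation_stochastic_switching(
    g1: Network, g2: Network, p: float, r: float, *, process: str = "flip"
) -> FixationResult:
    """Stochastic switching: the snapshot evolves by the given per-step
    ``process`` (Markovian flip with probability p by default, or an
    independent redraw favouring G1 with probability p).  rho averages over
    the N single-mutant states and the two equally likely initial
    snapshots."""
    if not (0.0 < p <= 1.0):
        raise ValueError(f"switching probability p must lie in (0, 1], got {p}")
    T1, T2, n = _pair_chains(g1, g2, r)
    S = T1.shape[0]
    M = stochastic_block_matrix(T1, T2, p, process)
    zero = np.array([0, S])
    one = np.array([S - 1, 2 * S - 1])
    x = solve_fixed_point(M, zero, one)
    idx = np.int64(1) << np.arange(n)
    rho = float((x[idx].sum() + x[S + idx].sum()) / (2 * n))
    return FixationResult(
        x, rho, {"mode": "stochastic", "p": p, "r": r, "process": process}
    )
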