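"""Full 2^N-state Markov chain of the birth–death process on a static network.

The population state is a bitmask over the N nodes (bit ``2^i`` set means node
i carries the mutant).  One step of the dynamics: a parent is chosen among all
nodes with probability proportional to fitness (resident 1, mutant r), then
one of the parent's neighbors is chosen proportional to edge weight and copies
the parent's type.  The resulting transition matrix has at most N+1 nonzero
entries per row and two absorbing states (all-resident, all-mutant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graphs import Network

__all__ = ["StateChain", "build_transition_matrix", "MAX_EXACT_NODES"]

# exact chains blow up as 2^N; this guard can be overridden explicitly
MAX_EXACT_NODES = 12


@dataclass(frozen=True)
class StateChain:
    """Transition matrix of the birth–death process over all 2^N states."""

    n_nodes: int
    T: sp.csr_matrix
    r: float

    @property
    def n_states(self) -> int:
        return 1 << self.n_nodes

    @property
    def full_state(self) -> int:
        return self.n_states - 1

    def state_index(self, mutant_set: int) -> int:
        """Row index of a mutant bitmask (node i contributes bit 2^i).

        The map is the identity on bitmasks, so the empty set is row 0 and
        the full set is row 2^N - 1; kept as a method to make the convention
        explicit and range-checked.
        """
        if not 0 <= mutant_set < self.n_states:
            raise ValueError(f"bitmask {mutant_set} out of range for N={self.n_nodes}")
        return mutant_set

    def index_state(self, index: int) -> int:
        if not 0 <= index < self.n_states:
            raise ValueError(f"index {index} out of range for N={self.n_nodes}")
        return index

    def single_mutant_states(self) -> np.ndarray:
        """Indices of the N states with exactly one mutant."""
        return np.array([1 << i for i in range(self.n_nodes)], dtype=np.int64)

    def dense(self) -> np.ndarray:
        return self.T.toarray()

    def to_csv(self, path) -> None:
        # debugging aid: dense dump, one row per state
        np.savetxt(path, self.dense(), delimiter=",")


def build_transition_matrix(
    g: Network, r: float, *, allow_large: bool = False
) -> StateChain:
    """Build the 2^N x 2^N birth–death transition matrix for fitness ``r``.

    Mutant-gain probabilities: a resident node v becomes mutant with
    probability ``(r / (r m + N - m)) * sum_{u mutant} A_uv / w(u)`` where m
    is the current mutant count.  Mutant-loss probabilities are the mirror
    image with parent fitness 1.  The diagonal completes each row to 1.
    """
    if r <= 0:
        raise ValueError(f"fitness r must be positive, got {r}")
    n = g.n_nodes
    if n > MAX_EXACT_NODES and not allow_large:
        raise ValueError(
            f"N={n} gives a 2^{n}-state chain; pass allow_large=True to override"
        )
    w = g.strengths
    if np.any(w == 0):
        bad = np.flatnonzero(w == 0)
        raise ValueError(
            f"nodes {bad.tolist()} have zero strength; the full chain requires "
            "every node to have at least one neighbor"
        )
    P = g.weights / w[:, None]  # P[u, v] = prob. that parent u replaces v

    n_states = 1 << n
    states = np.arange(n_states, dtype=np.int64)
    mut = ((states[:, None] >> np.arange(n)[None, :]) & 1).astype(float)  # (S, N)
    m = mut.sum(axis=1)
    D = r * m + (n - m)

    # inflow[s, v] = sum over mutant u of P[u, v]; outflow analog for residents
    from_mut = mut @ P
    from_res = (1.0 - mut) @ P
    gain = (r / D)[:, None] * from_mut * (1.0 - mut)  # resident v gains mutant
    loss = (1.0 / D)[:, None] * from_res * mut        # mutant v reverts

    bit = np.int64(1) << np.arange(n, dtype=np.int64)
    rows_g, cols_g = np.nonzero(gain > 0)
    rows_l, cols_l = np.nonzero(loss > 0)
    row_idx = np.concatenate([states[rows_g], states[rows_l], states])
    col_idx = np.concatenate(
        [
            states[rows_g] | bit[cols_g],
            states[rows_l] & ~bit[cols_l],
            states,
        ]
    )
    diag = 1.0 - gain.sum(axis=1) - loss.sum(axis=1)
    data = np.concatenate([gain[rows_g, cols_g], loss[rows_l, cols_l], diag])
    T = sp.coo_matrix((data, (row_idx, col_idx)), shape=(n_states, n_states)).tocsr()
    return StateChain(n_nodes=n, T=T, r=r)
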