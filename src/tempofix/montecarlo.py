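"""Monte Carlo estimation of fixation probabilities on switching networks.

The simulator follows the generative model directly — parent chosen
proportional to fitness among all N nodes, neighbor chosen proportional to
the edge weight in the currently active snapshot — so it also handles
snapshots with isolated nodes, which the exact solvers reject.  A parent
whose strength in the current snapshot is zero has nobody to reproduce into;
that step is a no-op (time advances, state unchanged).

Runs are simulated in vectorized lock-step batches; the run budget is split
into fixed-size chunks, each driven by an independent child stream spawned
from the root seed, so estimates are reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np

from .graphs import Network

__all__ = ["Schedule", "SimulationEstimate", "simulate_fixation"]

_CHUNK = 1 << 15  # runs per vectorized batch / RNG stream


@dataclass(frozen=True)
class Schedule:
    """Snapshot schedule: periodic (flip every tau steps) or Markovian
    (flip each step with probability p).  ``start`` selects the snapshot
    active at t=0: "g1", "g2", or "random" (uniform per run)."""

    mode: str
    tau: int | None = None
    p: float | None = None
    start: str = "g1"

    def __post_init__(self) -> None:
        if self.mode not in ("periodic", "markov"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        if self.mode == "periodic":
            if self.tau is None or self.tau < 1 or int(self.tau) != self.tau:
                raise ValueError("periodic schedule needs a positive integer tau")
        else:
            if self.p is None or not (0.0 < self.p <= 1.0):
                raise ValueError("markov schedule needs p in (0, 1]")
        if self.start not in ("g1", "g2", "random"):
            raise ValueError(f"start must be 'g1', 'g2' or 'random', got {self.start!r}")

    @classmethod
    def periodic(cls, tau: int, start: str = "g1") -> "Schedule":
        return cls(mode="periodic", tau=tau, start=start)

    @classmethod
    def markov(cls, p: float, start: str = "random") -> "Schedule":
        return cls(mode="markov", p=p, start=start)


@dataclass(frozen=True)
class SimulationEstimate:
    """Estimated fixation probability from repeated independent runs."""

    rho_hat: float
    n_runs: int
    stderr: float
    seed: int
    censored_runs: int = 0


def _neighbor_tables(g: Network) -> tuple[np.ndarray, np.ndarray]:
    """Per-node cumulative neighbor-choice distribution and zero-strength mask."""
    w = g.strengths
    isolated = w == 0
    safe = np.where(isolated, 1.0, w)
    P = g.weights / safe[:, None]
    P[isolated] = 1.0 / g.n_nodes  # never sampled (no-op), keep rows valid
    return np.cumsum(P, axis=1), isolated


def simulate_fixation(
    g1: Network,
    g2: Network,
    schedule: Schedule,
    r: float,
    n_runs: int,
    seed: int,
    max_steps: int = 10**8,
) -> SimulationEstimate:
    """Estimate the uniform-initialization fixation probability.

    Each run starts with a single mutant on a uniformly random node and
    iterates the birth–death process under ``schedule`` until one type
    fixates.  Runs exceeding ``max_steps`` are counted as censored and
    excluded from the estimate (rare when the aggregate network is
    connected).
    """
    if g1.n_nodes != g2.n_nodes:
        raise ValueError("snapshots must have the same number of nodes")
    if r <= 0:
        raise ValueError(f"fitness r must be positive, got {r}")
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    n = g1.n_nodes
    ncum = np.stack([_neighbor_tables(g1)[0], _neighbor_tables(g2)[0]])
    isolated = np.stack([_neighbor_tables(g1)[1], _neighbor_tables(g2)[1]])

    root = np.random.SeedSequence(seed)
    n_chunks = (n_runs + _CHUNK - 1) // _CHUNK
    streams = root.spawn(n_chunks)

    fixed = 0
    censored = 0
    for c in range(n_chunks):
        k = min(_CHUNK, n_runs - c * _CHUNK)
        rng = np.random.default_rng(streams[c])
        state = np.zeros((k, n), dtype=np.int8)
        state[np.arange(k), rng.integers(0, n, size=k)] = 1
        if schedule.start == "g1":
            snap0 = np.zeros(k, dtype=np.int8)
        elif schedule.start == "g2":
            snap0 = np.ones(k, dtype=np.int8)
        else:
            snap0 = rng.integers(0, 2, size=k).astype(np.int8)
        cur = snap0.copy()

        active = np.arange(k)
        t = 0
        while active.size:
            if t >= max_steps:
                censored += active.size
                break
            S = state[active]
            fit = np.where(S == 1, r, 1.0)
            total = fit.sum(axis=1)
            draw = rng.random(active.size) * total
            parent = np.minimum(
                (np.cumsum(fit, axis=1) < draw[:, None]).sum(axis=1), n - 1
            )
            snap = cur[active]
            ok = ~isolated[snap, parent]
            if np.any(ok):
                rows = ncum[snap[ok], parent[ok]]
                draw2 = rng.random(int(ok.sum()))
                nb = np.minimum((rows < draw2[:, None]).sum(axis=1), n - 1)
                runs = active[ok]
                state[runs, nb] = state[runs, parent[ok]]
            t += 1
            # advance the schedule
            if schedule.mode == "periodic":
                parity = (t // schedule.tau) % 2
                cur[active] = snap0[active] ^ parity
            else:
                flip = rng.random(active.size) < schedule.p
                cur[active] = np.where(flip, 1 - cur[active], cur[active])
            tot = state[active].sum(axis=1)
            done_mut = tot == n
            done = (tot == 0) | done_mut
            fixed += int(done_mut.sum())
            active = active[~done]

    n_eff = n_runs - censored
    rho_hat = fixed / n_eff if n_eff else float("nan")
    stderr = sqrt(rho_hat * (1.0 - rho_hat) / n_eff) if n_eff else float("nan")
    return SimulationEstimate(
        rho_hat=rho_hat,
        n_runs=n_eff,
        stderr=stderr,
        seed=seed,
        censored_runs=censored,
    )
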