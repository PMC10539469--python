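# Methods

## Model

Each of N nodes carries a resident (fitness 1) or mutant (fitness r > 0)
type. One birth–death step: a parent is drawn with probability proportional
to fitness among all N nodes; one of its neighbors in the *currently active*
snapshot is drawn proportional to edge weight; the neighbor adopts the
parent's type. Networks are undirected, weighted, without self-loops.

The population state is a bitmask s over the nodes; the per-snapshot
transition matrix T has, from a state with m mutants, mutant-gain entries
(r / (rm + N − m)) Σ_{u mutant} A_uv / w(u) for each resident node v,
mirror-image mutant-loss entries with parent weight 1, and a diagonal that
completes each row to 1, so each row has at most N + 1 nonzeros and the
all-resident / all-mutant states are absorbing.

Temporal variants and their propagators:

- **Periodic switching (G1, G2, τ)** — dynamics start on G1 and the
  snapshots alternate every τ steps; the fixation vector is the unique
  fixed point of (T1)^τ (T2)^τ with the absorbing boundary pinned.
- **Random arrival time** — the mutant appears at a time uniform over the
  2τ-step period. The two anchor vectors x\*(τ−1) and x\*(2τ−1) solve the
  cyclically rotated products T1 (T2)^τ (T1)^(τ−1) and
  T2 (T1)^τ (T2)^(τ−1); the remaining arrival phases follow by applying
  powers of T1 or T2, and the result is the average over the 2τ phases.
  At τ = 1 this reduces to the mean of the (G1, G2, 1) and (G2, G1, 1)
  fixed points.
- **Stochastic switching** — the chain state is (s, active snapshot). Two
  per-step snapshot processes are implemented:
  `process="flip"` (default): the snapshot flips with probability p, giving
  geometric dwell times with mean 1/p; `process="redraw"`: the next
  snapshot is drawn independently each step, G1 with probability p. The two
  coincide at p = 0.5 and at the extremes differ qualitatively: under
  "flip" the suppressor fraction of six-node pair sweeps increases
  monotonically with p toward the τ = 1 alternation limit, whereas under
  "redraw" it peaks at p = 0.5 because either extreme of p pins the
  dynamics to a single (mostly amplifying) snapshot. The published six-node
  stochastic-switching tallies correspond to the "redraw" process, which is
  what the reproduction tests and the acceptance sweep use; ρ averages over
  the two equally likely initial snapshots ("random initialization time")
  and the N single-mutant states.

All fixed points are computed by a direct solve of
(I − M_transient) x = M_transient→mutant-fixation · 1; uniqueness holds
because the propagators are row-stochastic with exactly two absorbing
classes on a connected (aggregate) network. A brute-force value-iteration
oracle (iterate x ← M x with the boundary re-pinned until the update falls
below 1e−13) is kept in the test suite as an independent route; the two
agree to better than 1e−9 on every ordered pair of connected 3- and 4-node
graphs for static, periodic and stochastic dynamics.

## Symmetry-reduced chains

For star (hub = node 0) + complete graph, the leaves are interchangeable in
both snapshots, so the chain lumps exactly onto (hub occupancy i, mutant
leaf count j): 2N states. For star + complete bipartite K_{N1,N2} (hub in
V1) the states are (i, j, k) with j mutants among the N1 − 1 non-hub V1
nodes and k among the N2 nodes of V2: 2·N1·(N2+1) states. The closed-form
entries follow from fitness-proportional parent choice and uniform neighbor
choice within the relevant class; uniform single-mutant initialization
weights the lumped single-mutant states by class multiplicity
(1, N1 − 1, N2)/N. Construction is cross-validated by a generic exact
lumping routine that aggregates the full 2^N chain under the node partition
and verifies, to 1e−12, that every micro state of an orbit has identical
outgoing probability into every target orbit (non-lumpable partitions are
rejected); reduced and full chains agree to 1e−10 for all configurations up
to six nodes.

## Classification

Amplifier/suppressor verdicts are decided on the operational nine-point
grid r ∈ {0.7, 0.8, 0.9} ∪ {1.1, 1.2, 1.3, 1.4, 1.6, 1.8}: an amplifier
must beat the Moran closed form strictly at all six r > 1 and fall below it
at all three r < 1; a suppressor reverses all nine inequalities; matches
within an absolute tolerance of 1e−9 count as ties (all ties ⇒ isothermal,
a tie elsewhere ⇒ neither). The tolerance sits three orders of magnitude
above the ~1e−13 accuracy of the direct solves and three below the smallest
genuine amplification effects observed in the six-node census (~1e−5).

The *static* six-node census additionally probes r ∈ {2, 3, 6, 10}
(`classify.R_LARGE_PROBES`). This reflects the classical, all-r notion of
amplification used for static censuses: three six-node graphs lie below the
Moran curve on the entire nine-point grid yet re-cross it between r = 2 and
r = 6, so they are "neither" rather than suppressors, leaving the known
tally of 100 amplifiers, 1 suppressor, 5 isothermal and 6 neither. The
switching-network sweeps use strictly the nine-point grid, which is the
operational definition under which the published sweep tallies were
produced.

## Six-node sweeps

All 112 connected unlabeled six-node graphs are enumerated exhaustively
(2^15 labeled graphs, connectivity filter, deduplication by the
lexicographically minimal adjacency bitstring over all 6! node
permutations — self-contained and exact at this size; the test suite
cross-checks against VF2 isomorphism). Every ordered pair of distinct
graphs (12432 pairs) forms a switching network after relabeling the second
graph by one uniformly random permutation drawn from a per-pair substream
of the sweep seed; sweeping all 6! labelings would be ~9·10^6 pairs and is
deliberately not attempted, so sweep tallies are reproducible in
distribution but not digit-exact across seeds (observed seed-to-seed
variation is a few tenths of a percent of the pair count).

Two facts keep the sweeps at ~10–30 s: per-graph matrices (and their τ-th
powers) depend only on the 112 canonical graphs and the grid, so they are
precomputed once; and relabeling conjugates a chain by the induced
permutation of state bitmasks, so each pair needs only fancy indexing, one
64×64 matrix product per grid point, and one batched 62×62 (periodic) or
126×126 (stochastic) solve.

## Monte Carlo

The simulator follows the generative model directly and therefore accepts
snapshots with isolated nodes (where exact chains are undefined because a
zero-strength parent has no neighbor distribution). A selected parent with
zero strength in the active snapshot yields a no-op step: the state is
unchanged and time advances. This preserves fitness-proportional parent
selection exactly; the model description does not fix this corner case, and
the no-op rule is one defensible reading. Fixation still occurs whenever
the aggregate network is connected.

Runs execute in vectorized lock-step batches of 2^15, each batch driven by
an independent child stream spawned from the root seed (chunk streams
rather than per-run streams; the same seed reproduces the estimate
bit-for-bit). Censoring at `max_steps` (default 1e8) is counted and
censored runs are excluded from the estimate; the standard error is
binomial. The engine is validated against the exact solvers at the
3-standard-error level for periodic, random-start and Markovian schedules
on 3–5 node pairs.

## Synthetic contact fixture

`generate_synthetic_contacts` emulates a time-stamped contact sequence over
a small node set: a random spanning tree is embedded in the event stream so
the aggregate graph is always connected; an `overlap` fraction of nodes
appears in both halves while the rest are confined to one half, exercising
both snapshot constructions (restriction to the common nodes vs. union with
isolated nodes). First-half timestamps lie in [0, 1), second-half in
[1, 2), with event counts balanced so the median-index split recovers the
construction. It does not emulate burstiness, circadian rhythm, repeated-
contact weight structure or degree heterogeneity of real contact data, so
passing tests demonstrate correctness of the splitting/construction logic,
not realism of any particular empirical setting.

The half-split is by event count (first ⌈M/2⌉ events), not by midpoint of
the time span, which is well-defined under bursty timestamps; events tied
with the boundary timestamp stay in the first half.

## Problem sizes and numerical choices

Exact full chains are capped at N = 12 (4096 states) unless overridden;
matrix powers use binary exponentiation on dense arrays. The acceptance
script runs the stochastic sweep at p = 0.5 (the value whose tally is
independent of the snapshot-process reading) with the full 12432-pair
protocol. Reduced-chain scans cover N up to 50 (star+complete) and part
sizes up to 10 (star+bipartite) in seconds to minutes. Monte Carlo
reproduction uses 2·10^5 runs per fitness value at N = 4, the same run
count per condition as the published simulation protocol.

## Known limitations

- Directed networks, death–birth or imitation updating, fixation times and
  weak-selection approximations are out of scope.
- Exhaustive enumeration stops at six nodes by design.
- Empirical contact datasets are not bundled; the temporal tooling operates
  on user-supplied TSV event lists or the synthetic fixture.
- The sweep tallies depend (weakly) on the per-pair relabeling draw; only
  the seed-conditional values are exactly reproducible.
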