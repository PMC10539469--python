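# tempofix

Exact and Monte Carlo computation of mutant **fixation probabilities** for
constant-selection birth–death dynamics on **switching temporal networks**,
with amplifier/suppressor classification and exhaustive small-network
experiments.

## The problem

In evolutionary graph theory a population of N individuals sits on the nodes
of a network. A single mutant of fitness r (residents have fitness 1) appears
on a uniformly random node; each discrete step a parent is chosen with
probability proportional to fitness among all nodes, one of its neighbors is
chosen proportional to edge weight, and the neighbor copies the parent's type
(birth–death updating). The **fixation probability** ρ(r) is the chance the
mutant lineage eventually occupies every node. On the complete graph this is
the Moran process with the closed form

    ρ_Moran(r) = (1 − 1/r) / (1 − r^(−N)),   ρ_Moran(1) = 1/N.

A network is an **amplifier of selection** if ρ(r) > ρ_Moran(r) for
advantageous mutants (r > 1) and ρ(r) < ρ_Moran(r) for deleterious ones
(r < 1); a **suppressor** if both inequalities are reversed; **isothermal**
if ρ equals the Moran value (regular networks). Under birth–death updating
almost all small static networks are amplifiers.

This package studies what happens when the network is **temporal**: two
snapshots G1 and G2 alternate either deterministically every τ steps
(switching network (G1, G2, τ)) or stochastically, flipping each step with
probability p. The state space of the dynamics is the set of 2^N mutant
configurations; fixation probabilities are the unique fixed point
x = M x of the relevant propagator (M = (T1)^τ (T2)^τ for periodic
switching, a 2·2^N block matrix for stochastic switching) with the two
absorbing configurations pinned to 0 and 1, solved exactly by direct linear
algebra. Symmetry-reduced (lumped) chains for the star+complete and
star+complete-bipartite families shrink 2^N states to 2N and 2·N1·(N2+1)
states, making N in the tens exact. A vectorized Monte Carlo engine covers
arbitrary snapshot schedules, including snapshots with isolated nodes, and
time-stamped contact data can be split into snapshot pairs by two standard
constructions.

The headline phenomenon: combining two *amplifying* static networks into a
rapidly switching temporal network frequently produces a *suppressor* —
a majority of six-node switching networks suppress selection at τ = 1, in
stark contrast to the static case where exactly 1 of the 112 connected
six-node networks is a suppressor.

## Worked example

```python
import tempofix as tf

g1, g2 = tf.make_star(4), tf.make_complete(4)
moran = tf.moran_probability(1.2, 4)
print(f"Moran (N=4, r=1.2): {moran:.6f}")
for tau in (1, 10, 50):
    rho = tf.fixation_switching(g1, g2, tau, 1.2).rho
    print(f"switching tau={tau:>2}:   {rho:.6f}")
cls = tf.classify(lambda r: tf.fixation_switching(g1, g2, 1, r).rho, 4)
print("verdict at tau=1:", cls.verdict)
est = tf.simulate_fixation(g1, g2, tf.Schedule.periodic(1), 1.2,
                           n_runs=200000, seed=0)
print(f"Monte Carlo tau=1: {est.rho_hat:.4f} +/- {est.stderr:.4f}")
```

prints

```
Moran (N=4, r=1.2): 0.321908
switching tau= 1:   0.320514
switching tau=10:   0.328888
switching tau=50:   0.335761
verdict at tau=1: suppressor
Monte Carlo tau=1: 0.3206 +/- 0.0010
```

Although the star is an amplifier (static ρ = 0.336427 here) and the
complete graph is the Moran baseline itself, alternating between them every
step yields ρ below the Moran value for r > 1 (and above it for r < 1):
a suppressor built from non-suppressing parts. Slower switching (τ = 10, 50)
recovers amplification and approaches the star's own curve. The Monte Carlo
estimate agrees with the exact τ = 1 value within one standard error.

A command-line interface mirrors the main experiments
(`tempofix census6`, `tempofix sweep6 --tau 1 --seed 1`,
`tempofix sweep6-stoch --p 0.5 --seed 1`, `tempofix scan-sc`,
`tempofix scan-sb`, `tempofix fixation`, `tempofix simulate`); every
subcommand emits CSV with a `#` header recording parameters and seed.

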