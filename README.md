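# braincontrol

Structural controllability, control energy, and input-node placement for
brain-like networks.

Structural brain networks — regions linked by white-matter tracts — can in
principle be steered between activity states by driving a few regions with
external signals (the *input nodes*). This package implements the network
control-theory toolkit for asking how many inputs are needed, how much
energy control costs, and where inputs should be placed so that control is
cheap. It is written for network neuroscientists and network scientists
working with binary structural connectomes (or any binary digraph), and
ships a seeded generator of connectome-like synthetic networks so every
analysis is reproducible without restricted imaging data.

## The model

Dynamics are linear, `x' = A x + B u`, with `A` the binary structural
adjacency matrix (entry `(j, i)` encodes the link `i -> j`) and `B` a unit
selector of the input set `S`. The core quantities:

- **Minimum driver signals.** The smallest number of independent signals
  guaranteeing structural controllability is `N_i = max(1, N_u)`, where
  `N_u` counts unmatched nodes in a maximum matching of the split-node
  bipartite graph (each node `v` becomes `v+`/`v-`; link `v -> w` becomes
  `(v+, w-)`).
- **Control energy.** For horizon `t_f`, the controllability Gramian
  `W_B(t_f) = ∫₀^{t_f} e^{Aτ} B Bᵀ e^{Aᵀτ} dτ` is positive definite iff
  `(A, B)` is controllable; the trace energy `ε(t_f) = Trace(W_B(t_f))`
  (reported as `log10 ε`) is the average-energy proxy — *larger trace,
  cheaper control*. It satisfies `Trace(W⁻¹) > N²/Trace(W)`.
- **Longest control chain.** `LCC = max_w min_{v∈S} d(v, w)`, the longest
  directed distance from a node to its nearest input. Energy rises sharply
  with the LCC, so placing inputs to shorten chains is the structural route
  to cheap control.
- **Placement.** Minimum inputs achieving `LCC ≤ ℓ` is a minimum
  distance-ℓ dominating set: solved exactly (branch and bound) on small
  networks and by greedy max-coverage otherwise, with a hub-first baseline
  for comparison. Because connectome hubs form a *rich club* (hubs wire to
  hubs), all-hub input sets cluster at mutual distance 1 and waste inputs;
  optimal sets mix low- and high-degree regions spread through the network.
- **Null models and motifs.** Degree-preserving double-edge swaps (trial
  budget `⌈(|E|/2)·ln(1/ε)⌉`, with optional rich-club destruction) isolate
  what the degree sequence alone explains, and a census of the two
  connected bidirectional 3-node patterns (mutual open path, id 78; mutual
  triangle, id 238) proxies path multiplicity between regions.

## Worked example

The bundled 5-node toy (edges `1→2, 2→3, 2→4, 4→5`) needs two signals, and
the two alternative matching-derived input sets differ in control cost:

```python
import braincontrol as bc

toy = bc.fig1_toy()
mr = bc.maximum_matching(bc.build_bipartite(toy))
print(mr.n_inputs)                                            # 2
print(bc.input_distances(toy, bc.InputSet([0, 2])).lcc)       # 3.0
print(bc.input_distances(toy, bc.InputSet([0, 3])).lcc)       # 2.0
print(bc.trace_energy(toy, bc.InputSet([0, 2])).trace_energy) # 2.4373015873015875
print(bc.trace_energy(toy, bc.InputSet([0, 3])).trace_energy) # 2.770634920634921
```

Inputs `{1, 3}` leave node 5 three hops from the nearest input (LCC 3),
while `{1, 4}` shortens every chain to at most two hops (LCC 2) — and the
shorter-chain scheme has the larger Gramian trace, i.e. needs less energy.

The same pipeline on a synthetic 90-region connectome, from the shell:

```bash
braincontrol simulate --preset brainlike --seed 3 --out net.csv
braincontrol controllability --network net.csv   # N_i = 1: one signal suffices
braincontrol place --network net.csv --lcc 1     # ~10% of regions as inputs
braincontrol motifs --network net.csv
```

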