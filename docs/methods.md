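# Methods

## Model and conventions

Networks are binary digraphs under linear time-invariant dynamics
`x' = A x + B u`. Adjacency entry `(j, i) = 1` encodes the directed link
`i -> j`, so the matrix is literally the `A` of the dynamics; the edge-list
reader documents this mapping. Connectome-style inputs are undirected:
binarization (`a_ij > 0 → 1`, diagonal discarded with a warning) followed
by bidirection (each undirected link becomes both directed links) yields a
symmetric structural matrix, on which in- and out-degree coincide.
Isolated regions are removed before analysis: they carry no links, so they
cannot affect chain lengths or energy, only inflate the driver count.

## Driver signals by maximum matching

The split-node bipartite graph (`v` → copies `v+`, `v-`; link `v -> w` →
edge `(v+, w-)`) is matched with Hopcroft–Karp (networkx), deterministic
for a fixed network. Unmatched in-copies locate where independent signals
must attach, and `N_i = max(1, N_u)`. `N_u` is matching-invariant, but the
unmatched *set* is not; `enumerate_unmatched_sets` exhaustively enumerates
the alternatives on small networks (this is how the toy's two input sets
`{1,3}` and `{1,4}` are exhibited, and it doubles as a test oracle).

## Gramian and energy

`W_B(t_f)` is computed by the Van Loan block-exponential: the exponential
of `t_f · [[-A, BBᵀ], [0, Aᵀ]]` has blocks `F12`, `F22` with
`W = F22ᵀ F12`. This is exact up to `expm` accuracy and valid for unstable
`A` (the integral is over a finite horizon, so Lyapunov solvers do not
apply); tests cross-check it against adaptive quadrature of the defining
integral to 1e-8 relative error. `W` is symmetrized to machine tolerance,
and overflow of the exponential raises with advice to shrink `t_f`.
Default horizon `t_f = 1`.

Controllability is decided by `λ_min(W) > tol` with
`tol = n · ε_machine · λ_max(W)` by default — the Gramian of dense networks
is ill-conditioned, so raw positivity of the smallest computed eigenvalue
is unreliable. The Kalman rank of `[B, AB, …, A^{n−1}B]` (with per-block
rescaling) is reported as an independent cross-check.

Trace energy `ε(t_f) = Trace(W)` is reported as `log10 ε`, unnormalized.
The trace is additive over input columns, so all `n` single-input energies
come from one block exponential on `(Aᵀ, I)` — the per-node scan of a
90-region network costs one 180×180 `expm`, not 90 Gramians; linearity
makes this bit-identical to per-node integration. `Trace(W⁻¹)` is exposed
only as a validation inequality (`≥ N²/Trace(W)`, equality at `W ∝ I`);
it is not a production metric because near-singular Gramians make it
uncomputable on realistic networks.

## Longest control chain and placement

`LCC(S) = max_w min_{v∈S} d(v, w)` with distances measured *from* inputs
along link direction — invisible on symmetric networks, decisive on
general digraphs. Unreachable nodes yield an infinite LCC rather than an
error; placement uses this as an infeasibility signal.

Minimum inputs for `LCC ≤ ℓ` is the minimum distance-ℓ dominating set.
Exact mode (≤ 25 nodes) runs branch and bound over bitmask coverage sets,
branching on the uncovered node with the fewest coverers and enumerating
*all* minimum covers (capped at 200); greedy mode is max-coverage with
ties broken by higher degree then lower index, or by a seeded uniform
draw in the randomized variant used for the input-set census. The
hub-first baseline adds nodes in descending degree order until the target
LCC is reached.

An ℓ-cover guarantees short chains but not controllability (a covered
node behind a branching "dilation" can still be unsteerable), so every
returned set is re-verified with the Gramian test; on failure the set is
augmented with unmatched matching nodes and re-checked, with the
augmentation recorded in the result. Exact mode prefers, among equal-size
minimum covers, one that already passes the test. Verification is skipped
above 200 nodes, where the check is costly and — for the symmetric
connected networks this package targets — redundant.

Dispersion `d_i` of an input set is the mean directed shortest-path
distance over ordered input pairs (finite pairs only; undefined for
singletons). The size-matched hub set used for the rich-club contrast is
a degree-descending prefix of the same cardinality as a reference set and
is deliberately *not* augmented.

## Null models

Degree-preserving randomization uses double-edge swaps with a trial
budget of `⌈(|E|/2)·ln(1/ε)⌉`, `ε ∈ [1e-7, 1e-6]`, counting *attempted*
swaps (proposals rejected for creating self-loops or duplicate links
consume budget; the formula prescribes trials, not successes). Symmetric
networks are swapped on their undirected skeleton with both directions
written back — arc-wise swapping would destroy the bidirectionality the
networks possess by construction; asymmetric digraphs are swapped
arc-wise, preserving in- and out-degree separately.

Rich-club destruction repeatedly exchanges a hub–hub link and a
low–low link for two hub–low links (degree-preserving; hub–hub count
non-increasing) until no swappable pair remains or the budget is spent.
"Hubs" default to the top 10% of nodes by degree — a conventional cutoff,
exposed in `RewiringConfig`. The ensemble comparison `n_i_rand(ℓ)`
averages the greedy placement fraction over 20 randomized replicates
(rewiring followed by rich-club removal), all driven by one seed.

## Motif census

On symmetric networks the two connected 3-node patterns are counted in
closed form — triangles `T = trace(A³)/6` and open mutual paths
`Σ_v C(k_v, 2) − 3T` — with brute-force induced-triple enumeration as the
test oracle. Counting is of induced subgraphs. Asymmetric digraphs fall
back to enumeration, with connected triads containing any non-mutual link
tallied separately as `other` and excluded from `M`, which is defined on
bidirectional networks.

## Synthetic networks

The brain-like generator emulates the structural envelope of 90-region
DTI connectomes: ~1150 directed links (≈575 undirected connections, mean
degree ≈ 12.8 — the link counts reported for such data are consistent
only with directed counts, i.e. `c = |E|/N`), minimum degree 1–6, hub
maxima up to 43, mean internode distance ≈ 2.0–2.1, one isolated region,
and a rich club. Degrees are sampled from a clipped lognormal
(σ = 0.6, which lands the normalized heterogeneity `H/c` in ≈ 0.5–0.7)
with a couple of forced degree-1–3 leaves, summed exactly to the link
target; the sequence is realized exactly by Havel–Hakimi, randomized with
5|E| double-edge swaps, made connected by degree-preserving
cross-component swaps, and given a rich club by swapping peripheral
attachments of non-adjacent hub pairs into hub–hub links
(`rich_club_strength` scales how many). A seeded node permutation
finishes, so isolated regions are not positionally special. The generator
reproduces the summary statistics it targets, not the geometry, spatial
embedding, weights, or subject-level individuality of real connectomes —
passing tests demonstrate the method's behavior under the stated
structural conditions, not on any individual's brain.

Degree heterogeneity is `H = max(H_in, H_out)` with
`H = (1/(rN²)) Σ_ij |k_i − k_j|`: the absolute value is required (the
signed double sum is identically zero), and the normalization constant
`r` is a free parameter (default 1; `r = c` gives the density-normalized
variant in which connectome values fall around 0.5–0.7).

The rich-club chain fixture (16 nodes: a bidirected 4-clique, three of
whose members carry 4-node pendant chains) is the minimal deterministic
instance where hub-first placement provably wastes inputs: the clique
saturates the degree ranking while the chain tails stay uncovered.

## Pipeline statistics

Adjacent LCC strata of the single-input scan are compared with two-sided
Wilcoxon rank-sum tests (scipy `mannwhitneyu`): exact null distribution
for tie-free strata of ≤ 10, otherwise the midrank normal approximation
with continuity correction; fully tied strata return p = 1 at the null
mean. Strata with fewer than two members are skipped with a warning. No
multiple-testing correction is applied across strata pairs. The study
runner fans a single seed out to per-stage generators via
`numpy.random.SeedSequence`, so reports are bit-reproducible; per-network
failures are isolated and logged, not fatal.

## Problem sizes and limitations

Tests and the acceptance script use 90-node networks (7-network
ensembles, 20-replicate null ensembles), where the full pipeline runs in
seconds. Exact placement is restricted to ≤ 25 nodes; at 90 nodes the
greedy cover is the operative method, so reported `n_i(ℓ)` are
near-minimal upper bounds, not certified optima. Energy magnitudes grow
like `e^{2λ_max(A) t_f}`, so `log10 ε` values on dense 90-node networks
sit around 6–12 and comparisons should stay within a fixed network and
horizon. Weighted controllability, observability, dedicated-input
(minimum-node) control, and energy-optimal trajectory synthesis are out
of scope.
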