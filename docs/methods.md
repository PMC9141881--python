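# Methods

## The problem

In a functional network — a brain, a gene-regulatory circuit, an evolved
digital controller — the information that determines behavior is rarely
stored in a single node. It can be *fragmented* across several nodes, and it
can be *encrypted*: a set of nodes may jointly determine a downstream value
while each member, viewed alone, is statistically independent of it (the XOR
/ one-time-pad situation). `infofrag` locates such information with plain
Shannon information theory, given full phenotypic data: the joint state of
every node recorded over time.

## Information measures

All quantities are in bits. From a recording we build maximum-likelihood
probability tables by counting joint states (the week-of-weather estimate:
four rainy days in seven give p = 4/7), then

- entropy `H(X) = -Σ p_i log2 p_i`,
- joint entropy `H(XY)` over composite states,
- shared entropy `I(X;Y) = H(X) + H(Y) − H(XY)`,
- co-information `I(A;B;C) = I(A;C) + I(B;C) − I(AB;C)`, which may be
  negative — negativity is the signature of synergy/encryption,
- a three-circle entropy Venn decomposition computed purely from joint
  entropies by inclusion–exclusion.

Estimates are plug-in, with no bias correction: the intended inputs are
complete recordings of (near-)deterministic networks, where the joint
support is small and fully observed, not sub-sampled neural data.

## Distinct informative sets and fragmentation

For a feature `Y` and a pool of m predictor nodes, a *distinct informative
set* (DIS) at threshold θ ∈ [0,1] is an irreducible subset `S` with
`I(S;Y) ≥ θ·H(Y)`; irreducible means no proper subset also qualifies.
*Fragmentation* `F_θ(Y)` is the size of the smallest DIS, `−1` when even the
full pool fails the threshold, and `0` for a zero-entropy feature (there is
nothing to predict; such features are also flagged and their normalized
matrix cells set to 1.0 so they render as trivially explained rather than as
missing information).

The search enumerates the 2^m − 1 non-empty subsets smallest-first,
lexicographically within a size, pruning supersets of already-found DISs.
The subset stream order is the canonical column order of the *fragmentation
matrix* (features × subsets, raw bits and H(Y)-normalized), which makes
"the first column reaching θ" a deterministic lookup that agrees exactly
with the direct search. Exhaustive enumeration is capped at pools of 16
nodes (65,535 subsets) with an explicit override.

Numerical choices: θ-comparisons use an absolute slack of 1e-9 to absorb
floating-point noise; shared entropies are clipped at zero; subset
entropies are computed from mixed-radix integer codes with memoization, so
the DIS search, matrix fill and flow labels share work.

## Information flow graphs

When predictors are the network state at t−1 (inputs + memory-before) and
features the state at t (outputs + memory-after), DIS collections at θ = 1
trace information flow. Each member of each DIS sends an edge to its
target; an edge is *necessary* (black) when its source sits in every DIS of
the target, *possible* (red) when redundant predictive sets leave causation
unresolved. Edge labels are single-source proportions
`I(source;target)/H(target)` — deliberately so, which is why both edges
into an XOR-decrypted node carry the label 0. All irreducible DISs are
kept, not just minimal-size ones: redundancy information feeds the
necessary/possible classification downstream. Zero-entropy nodes are
hidden; a nonzero-entropy target with no DIS (possible for stochastic or
trimmed recordings) is flagged unexplained rather than dropped.

If the substrate's wiring is known, the *connectome* (a link wherever some
gate reads the source and writes the target; for recurrent networks,
wherever the weight is nonzero) prunes coincidental predictions: a DIS is
removed iff any member lacks a physical link to the target. Redundancy the
wiring supports on all sides stays red.

*Flow complexity* is the total edge count of the graph.

A note on matrix sizes: for the n-Back flow analysis the feature side has
13 nodes (5 outputs + 8 memory) and the predictor side 9 (1 input +
8 memory), so the flow matrix built from the definitions is 13 × 511;
output-only matrices against the 8 memory nodes are 5 × 255. Statements
elsewhere of a 9 × 8192 flow matrix are not consistent with these
definitions (they transpose the sides and include the empty set); this
implementation follows the definitions.

## Testbed

**Substrates.** Both brains map T0 = [inputs, memory-before] to
T1 = [outputs, memory-after] with 8 memory nodes.

- *Markov Brains*: sparse networks of 2–4-input/2–4-output lookup-table
  gates decoded from a byte genome; colliding writes OR. Decoding scans for
  the start codon (42, 213); the gene layout after the codon — 1 byte
  #inputs (mod 3 + 2), 1 byte #outputs (mod 3 + 2), 4 + 4 address bytes
  (mod layout size), then 2^#in × #out table bytes (mod 2) — is this
  package's own frozen convention, chosen so decodes are deterministic,
  reproducible and hand-checkable. Truncated trailing genes are skipped, so
  decoding is total on arbitrary byte strings.
- *RNNs*: single-layer fully connected `Y_i = tanh(Σ_j w_ij X_j + c_i)`
  with genome bytes mapped linearly to weights in [−1, 1] and biases in
  [−3, 3]. Outputs and recurrent memory are discretized (≤ 0 → 0, > 0 → 1;
  exactly 0 maps to 0), which turns the network into a finite-state
  deterministic map and makes θ = 1 analysis well-posed.

**Tasks.**

- *n-Back*: echo the input bit at delays {1, 3, 5, 7, 8}; 25 lifetimes of a
  33-bit i.i.d. uniform string; the first 8 updates are unscored,
  unrecorded warm-up; fitness = correct answers / total answers (random
  guessing: 0.5).
- *Block Catch*: a 32 × 20 world with lateral wraparound; blocks of sizes
  {2, 3, 4} fall 1 unit and drift 1 unit left or right per update for 31
  updates; the agent is a 6-unit paddle whose sensor mask is `S S _ _ S S`.
  Catch size-2 and right-moving size-3 blocks, avoid the rest; a catch is
  any body/block overlap at landing. All 3 × 2 × 20 = 120 (size, direction,
  start) combinations are one evaluation; fitness = correct decisions /
  120. Ten binary world features (to-be-caught, moving-left, four size
  indicators including the never-used size-1 control, and the four
  direction × decision conjunctions) are recorded each update.

Design points the task description leaves open, frozen here: the paddle
body equals the 6-unit sensor span; motor outputs (1,0)/(0,1) move one unit
left/right and (0,0)/(1,1) hold; within an update the order is sense →
think → move → block advances; the agent starts at x = 0. These choices
affect individual trajectories, not the analysis method.

**Evolution.** Population 100, tournament size 5, generational replacement
with every offspring mutated (no elitism — the simplest reading of plain
tournament selection). Genomes start at 5000 random bytes (six start
codons seeded for Markov substrates); point mutations at 5e-3 per site
redraw a byte uniformly, copy-insert and delete events at 2e-5 per site
move segments of 128–512 sites, and length is clamped to [2000, 20000] by
skipping violating events. Lineages record genomes, fitnesses and parent
pointers each generation so the line of descent of any final individual can
be walked to generation 0. Mutational robustness of a genome is
`R = ⟨B⟩ / B0` with ⟨B⟩ the mean fitness of 100 independent mutants.

## Synthetic data and what passing tests show

The generator-and-testbed produces *complete, noise-free, discrete*
recordings from deterministic or stochastic stub agents. That matches the
setting the method is designed for and lets every analysis stage be checked
against hand-computable fixtures (shift-register chains, XOR delay cycles,
planted k-node parity features whose strict subsets carry exactly zero
bits). It does not emulate sub-sampled observations, continuous-valued
states, measurement noise, or unobserved confounders — on such real data
the plug-in estimates would be biased and θ = 1 sets would rarely exist, so
passing tests here say nothing about those regimes.

## Reduced problem sizes

Full-scale campaigns (hundreds of replicates evolved for 20,000–40,000
generations) are far beyond a single-workstation run, and the specific
evolved networks from such campaigns cannot be regenerated here. The
package's study driver therefore runs a deliberately scaled-down version:
20 replicates of population 100 for 60 generations on Block Catch, then
flow complexity and robustness (100 mutants) per best-of-replicate brain.
At this scale the best brains are good but typically imperfect solvers, and
the complexity–robustness relationship is checked as a *sign* property of
the rank correlation, not as a numeric effect size. Pilot runs during
development showed that at ~25 generations the evolved behavior is still
mostly unstructured and the correlation, while negative, is weak; ~60
generations gives the study usable statistical power while staying within a
few minutes of CPU time.

## Known limitations

- Exhaustive DIS search scales as 2^m; pools beyond 16 nodes need pruning
  upstream (no greedy/heuristic search is provided).
- Plug-in estimates have positive bias on small samples; there is no
  significance testing of matrix cells.
- Partial information decompositions (synergy/redundancy splits beyond
  co-information) are intentionally out of scope.
- The Venn decomposition is limited to three variable sets.
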