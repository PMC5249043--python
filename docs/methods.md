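# Methods

This note documents the models, algorithms, parameter choices and numerical
conventions behind `physteiner`, and what the synthetic benchmarks do and do
not demonstrate.

## Drug similarity networks

Drugs are binary feature vectors partitioned into category blocks (the
default layout is 881 chemical + 719 therapeutic + 775 protein + 1385
phenotype = 3760 columns). The complete DSN places an edge between every
drug pair with Jaccard dissimilarity cost `c_ij ∈ [0, 1]` and gives each
vertex the prize `p_i = Σ_{j∈T, j≠i} (1 + c_ij)^{-1} / |T|` relative to the
terminal set T. Conventions:

* The prize formula divides by |T| for terminals too, although their sum has
  only |T|−1 terms; the formula is applied verbatim, so terminal prizes are
  bounded by (|T|−1)/|T|.
* PCST requires strictly positive edge costs, but identical feature vectors
  give c = 0; costs are clamped below at 1e−9 during assembly.
* A pair of drugs with no recorded features has undefined Jaccard
  similarity; assembly assigns cost 1 (maximally dissimilar) and warns.
  The scalar `jaccard_cost` raises instead, leaving the policy to callers.
* Prizes are computed from the complete graph's pairwise costs and frozen
  before sparsification: they describe drug-to-class similarity, not the
  surviving topology.
* Vertices are ordered lexicographically by drug id everywhere; all
  tie-breaks below inherit this order, which makes every stage deterministic
  given its seed.

## Sparsification

**MST augmentation.** The minimum spanning tree (Prim, ties broken by
(cost, vertex-id pair)) is kept and the remaining edges are scanned in a
seeded random order, each added with probability `Pro` (default 0.5),
re-scanning until exactly `De` edges (default 1500) are present. Costs play
no role in the addition step, so the output reproduces the complete graph's
cost histogram.

**Two-threshold deletion.** Every edge with cost below t1 is removed
unconditionally; the survivors below t2 are scanned in ascending (cost,
vertex-id pair) order and removed unless removal disconnects the graph
(checked per edge by a linear-time traversal). Every surviving sub-t2 edge
is therefore a bridge. The unconditional first pass exists to keep the
number of connectivity checks small; a t1 that disconnects the graph is an
error, reported with the offending value.

**Data-driven thresholds.** For synthetic data the pipeline derives
(t1, t2) from the cost distribution: t2 is a high quantile (default 0.99)
and t1 is the 0.95 quantile capped at the exact connectivity bottleneck —
the minimum edge cost of the *maximum* spanning tree, which is the largest
t1 for which the first pass provably preserves connectivity. Fixed
thresholds (0.9 / 0.95, appropriate for the reference drug data) can be
supplied instead.

## PSIA

One terminal is drawn as the sink with probability proportional to the
rank-reversed total incident cost: ranking terminals by
`l(i) = Σ incident costs` ascending, the rank-i terminal gets weight
`l(|T|−i+1) / Σ_j l(j)`, so cheaply attached (well-connected) terminals are
likelier sinks. All other terminals inject flux I0.

Each iteration: (1) net costs `C_ij = c_ij − p_i/d_i − p_j/d_j + 2N` with
`N = max p` are recomputed on the current graph (cuts change degrees); since
`p/d ≤ N`, C is positive whenever c is. (2) Pressures solve the network
Poisson equation with conductances `g = D/C`, sink pressure pinned to 0; the
reduced symmetric positive definite system is solved by a sparse direct
factorisation (residuals are at machine precision, well below the 1e−8·I0
conservation tolerance the tests enforce). The solve is restricted to the
sink's connected component; detached non-terminal fragments carry no flux
and are dropped at the end. (3) Fluxes `Q = g·ΔPr` update conductivities via
`D ← D + α|Q| − μD`. (4) Edges with `D < ε` are cut in ascending conductivity
order, except that a cut which would disconnect any terminal from the sink is
skipped — the output must span all terminals and removed edges never return.

Defaults: α = 1.0, μ = 0.3 (μ < 1 keeps conductivities positive), ε = 0.01,
K = 50 iterations, I0 = 1.0, initial conductivities uniform in (0.5, 1.5).
The random initialisation is essential: DSN net costs are nearly uniform,
and identical conductivities can make the Poisson system ill-conditioned.
The flux-reinforcement fixed point is `D* = α|Q|/μ`, so with the defaults an
edge must sustain |Q| ≳ ε·μ/α = 0.003 to survive indefinitely. Cutting is
applied every iteration (a literal reading of "update and cut K times"); a
switch allows cutting only once after the final update. After K rounds the
sink's component is reduced to its minimum spanning tree under the original
costs — no leaf pruning is applied, so low-value non-terminal leaves may
remain; this keeps the finalisation exactly "MST of the surviving
subnetwork". Multiple runs derive per-run seeds from
`SeedSequence([master, run_index])` and are independent by construction.

Because the dynamics concentrate flow on paths that are short with respect
to the *net cost* C, PSIA is a heuristic: it needs neither to find the
prize-collecting optimum nor to include every profitable detour. The test
suite asserts only feasibility (terminal-spanning trees) and that objectives
never beat the exhaustive optimum, and reports the mean optimality gap.

## GW

The multi-terminal reduction roots the instance at a uniformly random
terminal and boosts every other terminal's prize to `M = Σ_e c_e + 1`; a
boosted component's surplus cannot be exhausted before the deficits on some
root path close, so all terminals provably end in the root component.

Growth is *event-driven*: instead of iterating a fixed step Δ, each round
advances time exactly to the next event — an active edge's deficit reaching
0 (deficit decreases by Δ per adjacent active component, 2Δ when both sides
are active) or an active component's surplus reaching 0. This is the Δ → 0
limit of the discrete loop and removes an arbitrary constant that would
otherwise influence results. Simultaneous events are resolved by
deactivating exhausted components first, then merging closed edges in
ascending vertex-id-pair order. A fixed-step reference mode (which
fast-forwards through uneventful steps but is event-for-event identical to
the naive loop) exists purely to validate the equivalence on small
instances. An edge is active only while its endpoints lie in different
components; internal deficits are frozen. The root component's merge edges
form its tree.

Strong pruning computes bottom-up net worths
`NW(v) = prize(v) + Σ_children max(0, NW(u) − cost(v, u))` with the boosted
prizes and deletes every subtree whose net worth cannot pay its connecting
edge. The pruned tree itself is the identified subnetwork — no MST
post-processing — because the point is which drugs appear, not squeezing the
last objective decrement.

## Evaluation and candidate ranking

`RI = (I_c + N_nc) / (|V| − |T|) × 100` is computed by explicit set
counting; a closed-form variant from summary counts
(|V|, superclass size, |T|, |V'|, I_c) backs the published-table worked
examples, and the two are tested to agree. Best-per-DSN selection maximises
RI with ties broken by smaller subnetwork then smaller objective (small
subnetworks are preferable for repositioning analysis). Candidates are
out-of-superclass drugs occurring in at least 2 selected subnetworks
(per-DSN best subnetworks of the two-threshold variant, when present).
Dispersion diagnostics use the population standard deviation convention and
are reported both raw and ×100.

An exhaustive PCST solver (all terminal-containing vertex subsets with
connected induced subgraph, MST of each) serves as the optimality oracle,
guarded to ≤ 12 vertices.

## Synthetic data

The generator plants classes in a binary matrix: each class reserves a
disjoint run of `round(shared_core_fraction × n_features)` columns (default
fraction 0.05) which members activate with probability 0.9, while every
other entry is background noise. Background rates are heterogeneous by
default — each drug draws its rate uniformly from (0.1, 0.4) — because real
pharmacological annotation density varies strongly between drugs, and it is
precisely this heterogeneity that spreads pairwise Jaccard costs over a
broad band (bulk ≈ 0.6–0.95) instead of collapsing them onto a point. With
a degenerate (single-rate) background, threshold-based edge deletion cannot
both remove most edges and preserve connectivity; a scalar rate remains
available for controlled experiments. Class members are systematically
cheaper to each other and carry elevated prizes toward their subclass,
which is what makes subnetwork recovery testable.

What the synthetic benchmark does **not** emulate: overlapping subclass
membership, correlated features within category blocks, realistic marginal
feature frequencies, and heavy-tailed class sizes. Passing tests therefore
demonstrate algorithmic correctness and the qualitative PSIA-vs-GW
comparison under planted structure, not performance on real pharmacological
data.

## Problem sizes and defaults used in the checks

The default study configuration mirrors the reference analysis: 548 drugs,
nine subclasses with terminal-set sizes (22, 12, 13, 4, 9, 15, 8, 16, 8),
3760 feature columns, MST augmentation to 1500 edges, three PSIA runs and
one GW run per DSN. The planted-network comparison in the test suite runs
at 200 drugs with five subclasses and 20 seeds, and the solver-vs-oracle
checks use 200 random instances of at most 8 vertices — sizes chosen so the
whole suite exercises every code path at desk scale while the full 548-drug
construction is still covered by the structural checks and the acceptance
script.

## Known limitations

* PSIA's per-iteration cut guard costs one traversal per candidate edge; on
  very dense graphs with aggressive ε this is the dominant cost.
* The exhaustive oracle is exponential and guarded; no exact solver for
  medium instances is provided.
* The Rand Index treats all non-terminal vertices equally; it is not
  adjusted for chance and is not comparable across different |T| except in
  the aggregate way it is used here.
* Sink sampling is the only stochastic element separating repeated PSIA
  runs on the same DSN; on instances where one terminal dominates the
  probability mass, the three runs can coincide.
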