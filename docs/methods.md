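# Methods

## Model and update semantics

A Boolean network is a directed graph with one truth table per regulated
node. Truth-table rows are indexed by the input tuple read as a binary
number with the first listed input as the most significant bit; this
convention is fixed so files round-trip deterministically (published table
dumps with a different row order must be mapped by the user). Nodes with no
incoming edge are inputs and are clamped — OFF by default, modeling the
nominal no-stimulus condition; per-node clamp overrides reproduce
ligand-ON conditions. Node ids are case-sensitive strings; all tie-breaking
downstream uses lexicographic order on states in network node order.

Synchronous update evaluates every regulated node simultaneously on the
previous state. Because the state space is finite and the map
deterministic, every trajectory ends in a fixed point or limit cycle;
`run_to_cycle` finds the first repeated state by exact hashing (default
horizon 10,000 states, far beyond what small and mid-size models need) and
raises an explicit error rather than truncating. Asynchronous update is a
random-permutation sweep: each step updates every regulated node once, in a
fresh uniform random order, each node seeing the partially updated state.
A sweep keeps step counts comparable to synchronous runs; updating a single
random node per step is the main alternative and the literature rarely
distinguishes them for reachability-style questions — this was a genuinely
open choice.

The stochastic-input protocol sets each input node ON independently with a
given probability at every step (1,000 steps by default), then measures
per-node mean activity over the last 100 steps and bins it into three
categories on whole-percent ranges: 0–9% → 0, 10–29% → 1, 30–100% → 2
(activities are rounded to whole percent first, so 0.095 falls in
category 1).

## Attractor landscape

Landscapes are estimated from initial states drawn uniformly over
assignments of the free (regulated) nodes, clamps held fixed; each state is
run to its cycle, and attractors are pooled by canonical form — the
rotation of the cycle starting at its lexicographically smallest state.
Attractor identity is exact equality of full-dimension canonical
sequences; since edge deletion never changes the node set, states remain
comparable across perturbed networks, and this is the strictest reading of
"the primary attractor is preserved". The primary attractor is the one
with the largest basin count, ties broken by lexicographically smallest
canonical sequence (deterministic across platforms).

`enumerate_attractors` is an independent exact oracle for ≤ 20 free nodes:
it builds the full successor array, finds recurrent states by peeling
zero-in-degree states from the functional graph, and sizes basins by
reverse BFS. The sampling estimator with exhaustive coverage must agree
with it exactly; this dual-route check runs in the test suite and the
acceptance script on 50-network ensembles.

Basin sampling is by rejection: uniform free states are kept if they
converge to the target attractor. If the acceptance rate over a 10,000-draw
probe falls below 10⁻³ the sampler fails explicitly rather than spinning.

## Decomposition

The algorithm takes two seeds — one for initial-state/basin sampling, one
for deletion order — mirroring the two robustness axes a study should
report. Steps: estimate the landscape and fix the primary attractor; sample
the basin-state panel once on the original network and reuse it for every
test (the panel is deliberately not re-sampled per deletion); remove
insignificant edges (`l_0 = l_1`) to a fixpoint; then repeatedly build the
candidate set of edges whose single deletion preserves the primary, consume
it in uniform random order with re-testing on the current reduced network
(failed candidates are discarded until the next rebuild), and stop when a
rebuild finds no deletable edge. Termination guarantees minimality: no
single core edge is deletable from the final network.

Edge deletion fixes the deleted input at 0 in the target's table, matching
the global inputs-OFF nominal condition; the fixed value is configurable to
1, and projections commute, so deletion order never changes the resulting
tables. Preservation demands that *all* sampled basin states reach the
exact original primary cycle; a fraction threshold exists
(`preserve_fraction`, default 1.0) for sensitivity analyses. A trajectory
that exceeds the horizon counts as not preserved.

`verify_decomposition` re-checks the definitional contracts from scratch:
the core network (original minus all neighbor edges) preserves the primary
for every basin state; no single core edge is deletable; core and neighbor
partition the edge set with consistent provenance
(insignificant / candidate_deleted / retained).

`perturbation_novelty` deletes each core edge from the original network,
re-runs the basin panel, and reports the distinct non-primary attractors
and the fraction absent from the original attractor list — the bridge
between landscape-change evolvability and new-attractor evolvability.

## Topology and null models

Feedback loops are distinct simple directed cycles of 1, 2 or 3 nodes
(counted once per node set; logic and sign ignored). Degree heterogeneity
is the population variance of the total (in+out) degree distribution
divided by its mean. Characteristic path length averages directed
shortest-path lengths over reachable ordered pairs; unreachable pairs are
excluded rather than imputed (the underlying definition is silent, and
imputation would make the statistic depend on an arbitrary ceiling).
Components are counted weakly among nodes with at least one incident edge —
a disconnected regulator still belongs to its module. Both directedness
choices are switchable by passing a pre-built graph.

Null ensembles delete m random edges from the full network (control for
the core) or keep m randomly selected edges (control for the neighbor),
100 replicates by default. The observed statistic is a single value, so the
one-sided comparison is computed as a t-test of the null replicate values
against the observed value (t = (obs − mean)/sd, df = replicates − 1);
this reproduces p = 0.5 for a statistic centered on its null mean and is
the single-observation limit of the two-sample form. Zero-variance nulls
get a variance floor and a flag.

The 2×2 agreement test between two decompositions uses the uncorrected
chi-square statistic (so a perfectly diagonal 50/50 table scores 100 on
1 df) halved into a one-sided p for positive association, plus the Jaccard
index of the core sets.

## Canalization

A canalizing input forces the output at one of its values; all claimed
triples are verified exhaustively against the table. A *redundant* input is
one eliminated by exact two-level minimization (Quine–McCluskey via
sympy's `SOPform`, applied to the function and its complement): it appears
in no prime implicant of any minimal cover. For exact minimization this
criterion provably coincides with the input being fictitious
(`l_0 = l_1`) — a function that depends on an input cannot be covered
without it — so redundancy is strictly local and every redundant edge is
also insignificant for the dynamics. Consequently redundant links always
fall in the robust neighbor, and the interesting separation runs the other
way: the neighbor also contains locally *essential* edges whose loss the
global dynamics tolerates (see the REDUNDANT4 fixture). Broader redundancy
notions (e.g. partial schema redundancy of canalized inputs) would enlarge
the redundant set and can intersect the core; they are deliberately out of
scope because no exhaustively checkable formalization was available.

## Enrichment

Gene scores are means over the nodes mapping to each gene (nodes mapping to
several genes contribute to each; genes with no scored node are absent).
The normalized group score is group mean over universe mean and is
scale-invariant. The permutation test draws same-size random groups without
replacement and reports the one-sided p with the +1 finite-sample
correction, hence p ≥ 1/(n_perm + 1); the default direction is "greater".
Genes missing a numeric property are dropped pairwise in Pearson
correlations, with the effective n reported.

## Synthetic generator

The generator emulates the model class under study: regulated nodes draw
regulators from a fixed/Poisson/truncated-power-law in-degree distribution
and fill truth-table rows i.i.d. Bernoulli(p). Planted feedback loops are
wired first as copy gates and receive no further regulators, guaranteeing a
sustained limit cycle; without planting, random-bias tables frequently
collapse to fixed points and decomposition studies would have no
nontrivial primary attractor. Defaults used across the test-bed: 8–12
nodes, 1–2 inputs, Poisson(2) in-degrees, bias 0.5, one planted 2- or
3-loop. What the generator does **not** emulate: the long-tailed degree
distribution, nested canalizing logic, and modular organization of curated
signaling models — so green tests certify the algorithms' correctness
contracts, not biological conclusions about any real network.

## Study scales and determinism

Desk-scale defaults keep every check exact or tightly bounded: ensembles of
50 networks (≤ 12 free nodes, where exhaustive enumeration is the oracle),
basin panels of 200–500 states for synthetic studies (the 10,000-state
panel remains the default for real models), 100 null replicates, and
100,000 permutations where calibration is the point. Every stochastic
component takes an explicit seed; identical seeds give bit-identical
results, and statistical assertions use 3-sigma binomial/hypergeometric
bounds computed from the quantity under test.

## Known limitations

- Synchronous-update attractors only; the asynchronous sweep supports
  reachability experiments but the decomposition itself is defined on the
  synchronous landscape.
- Strict full-dimension attractor identity can classify a pure readout
  edge as core when its deletion only rewrites a non-feedback coordinate
  of the primary cycle.
- Sampled landscapes can miss attractors with basins ≪ 1/n_samples; the
  decomposition inherits that blind spot on large models.
- The redundancy criterion is the exact-minimization one discussed above;
  counts against looser illustrations of "redundant link" are not
  comparable.
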