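# Methods

## Model and problem

A synchronous Boolean network is `G = ⟨V, F⟩` with nodes `V = {v_1..v_n}`
and update rules `f_i : {0,1}^{k_i} → {0,1}` over each node's regulators;
`K = max k_i`. The global state `S(t)` advances as `S(t+1) = F(S(t))`,
all nodes at once. The package enumerates exactly the fixed points
(`F(S) = S`, attractors of period 1). Cyclic attractors are a non-goal:
nothing here bounds or detects periods above 1, and no claim is made
about them.

States are stored as name→value assignments with an explicit rendering
order (`PartialState`), not positional vectors. Equality and hashing
compare the assignment only; the order is presentation. This removes a
whole class of off-by-one errors when the same node appears at different
positions in different subnetwork scopes.

## Partition → local solve → composition

**Minimum essential blocks.** The default partition puts every node in
its own block; subnetwork `i` owns `v_i` and takes `C_i =
regulators(v_i) \ {v_i}` as free control inputs, so its scope has at most
`k_i + 1 ≤ K + 1` nodes. Regulators are read *syntactically* from the
parsed rule (a rule `a & !a | b` counts `a`), matching how indegree is
read off published rule sets; no don't-care elimination is applied.
Block and controls are kept as separate fields — the composition logic
needs the union (the scope) while the local solver needs the
distinction. User-supplied partitions (any disjoint cover of `V`) are
accepted and validated; the correctness of the composition does not
depend on the partition chosen.

**Local steady states.** A local steady state of a subnetwork assigns
the whole scope such that every *owned* node equals its rule's output;
controls are unconstrained. The SAT encoding emits, per owned node, one
clause for each truth-table row of `vars = R ∪ {v}` that falsifies
`v ↔ f(R)` — clause width ≤ `|R| + 1`, reproducing the `(K+1)`-SAT
structure of the problem. Truth-table CNF is preferred over Tseitin
because MEB scopes are tiny and it introduces no auxiliary variables, so
all-solutions enumeration with blocking clauses over the scope variables
cannot produce duplicate models. A self-regulating owned node keeps its
self-reference inside the constraint (the fixed-point semantics
`s_i = f_i(…, s_i, …)`), it is never treated as a control. The
truth-table expansion is guarded by a configurable regulator cap
(default 16).

The in-package solver is a DPLL with unit propagation and chronological
backtracking returning total models; at the clause counts produced here
(≤ `2^{K+1}` clauses of width ≤ `K+1` per owned node) nothing more is
warranted. The exhaustive enumerator (`2^{|scope|}` scan, cap 22) has
the identical contract and is the independent oracle in the test suite —
the two paths are never collapsed onto one implementation.

**Composition.** `a₁ × a₂` is defined when the two partial states agree
on their common nodes and yields the union assignment. Joining all
local sets, in any order, gives exactly the global fixed-point set
(order-independence is property-tested over random permutations). The
join is a hash join keyed on the restriction to the common nodes,
contractually identical to the quadratic double loop (also tested).
Output ordering is canonical — states sorted by their bit vector under
lexicographic node order — so results are byte-stable across join
orders.

## Composition order

The size of an intermediate composed set over accumulated scope `S` with
owned set `O` is bounded by (and for loop-free rules equals a constant
times) `2^{|S \ O|}` — one state per assignment of the not-yet-owned
frontier. Two greedy orders are provided:

- `determine_order` (the default first attempt): seed with the largest
  scope; repeatedly append the subnetwork whose scope overlaps the
  accumulated scope most. Overlap ties are broken by *fewest new scope
  nodes*, then smallest index. The tie rule matters: with
  smallest-index ties alone, 8 of 10 benchmark networks at `n = 200,
  K = 5` exceeded a 10^6 intermediate cap, while the fewest-new-nodes
  rule kept every peak ≤ 32768 on the same networks.
- `frontier_order` (automatic fallback, also selectable): append the
  subnetwork adding the fewest new scope nodes, ties by most overlap.
  This directly attacks the `2^{|S\O|}` bound and in practice keeps
  intermediates near the final fixed-point count.

The pipeline runs the overlap-greedy order first; if the intermediate
cap (default 10^6 states, checked *inside* the join loop so memory stays
bounded) is exceeded it retries once with the frontier order before
propagating the failure. Because the final set is order-independent,
the fallback changes cost, never results. Exhaustive order search is a
non-goal.

Internally the composition works on packed byte strings (one byte per
scope node) and materialises `PartialState` objects only for the final
result; per-join instrumentation (`JoinStep`: common set, input sizes,
output size, discarded states) feeds the verbose log and the redundancy
analyses in the tests.

On the bundled 6-node example, the printed 3-block partition
(`{v1,v2,v3} | {v5} | {v4,v6}`) yields local sets of sizes 3/2/2;
joining `A1` with `A2` first builds 3 intermediates of which 1 is later
discarded, while joining `A1` with `A3` first builds 4 of which 2 are
discarded; both routes end in the same two fixed points.

## The `.bnet` dialect

Accepted grammar: identifiers `[A-Za-z_][A-Za-z0-9_]*`, operators
`! & |` (precedence NOT > AND > OR), parentheses, constants `0`/`1`,
`#` comments, optional `targets, factors` header; one `name, expression`
line per node, node order = line order. Equivalence/XOR must be written
expanded (e.g. `(a & b) | (!a & !b)`); the programmatic AST offers
`Iff`/`Xor` and serialises them into the core operators. The round-trip
guarantee is semantic (identical node order, regulator sets and rule
truth tables), not textual. Parse failures raise distinct error types
naming the offending line. Zero-indegree nodes are only valid with
constant rules; a free external input is modelled as the identity
self-loop `v, v`. Node names are case-sensitive and whitespace-trimmed.
Fixed-point output is TSV (header = node names, one sorted 0/1 row per
state) or JSON (list of name→value maps); sorting makes output
bit-exact for comparison.

## Synthetic networks

`generate_random_bn` emulates the scale-free N–K random networks used to
stress-test attractor detection: indegree `k` drawn from `P(k) ∝
k^{-γ}` truncated to `{1..K}`, `k` distinct regulators uniform without
replacement (self-loops permitted), random truth table with bias
`P(row = 1) = b`. Defaults `γ = 2.5` and `b = 0.5` are the documented
defaults of the widely used R generator this emulates; both are exposed.
By default a table is redrawn until its output depends on every drawn
regulator (`require_relevant=True`, again mirroring the upstream
default): without it, minterm rendering collapses about a quarter of the
`k = 1` nodes to constants and the realised indegree distribution no
longer matches the drawn power law (measured mean 0.89 vs ≈ 1.3).
Generation is fully deterministic given the seed — identical configs
produce byte-identical `.bnet` text. No attempt is made to reproduce
the upstream package's RNG stream bit-for-bit, only the distributional
regime.

What the generator does *not* emulate: canalising/nested-canalising rule
biases, correlated in/out-degree, modular or bow-tie topology, and the
curated logic of published models. Green batteries on these networks
demonstrate correctness and scaling behaviour of the algorithm, not
biological realism of any particular model.

## Test and battery sizes

Exact checks run on the 6-node example and hand-crafted degenerate nets
(disconnected, all-constant, pure self-loop, oscillator, a net with
`2^n/4` fixed points). The statistical batteries use 200 random
networks (`n ≤ 15`, `K ∈ 2..5`) for pipeline-vs-oracle set equality,
500 random subnetworks (scope ≤ 12) for SAT-vs-exhaustive agreement, 50
networks for the `2^{|controls|}` counting law, and 10 networks per size
`n ∈ {50, 100, 200, 300}` at `K = 5` for completion and soundness.
These sizes keep the full suite in the low minutes while exercising
every code path at the scales where the composition behaviour actually
varies; the `n ≤ 15` bound on oracle comparisons is set by the `2^n`
oracle, not the pipeline.

## Known limitations

- Fixed points only; a network whose only attractors are cyclic returns
  an empty (and correct) result.
- Adversarial networks can exceed the intermediate cap under *both*
  greedy orders (the underlying problem is NP-hard; the cap turns
  blow-up into a clean diagnostic rather than an OOM).
- The truth-table CNF caps rules at 16 regulators by default; beyond
  that the encoding (not the algorithm) is the bottleneck.
- The `.bnet` reader covers the core dialect, not vendor extensions
  (multi-valued targets, probabilistic rule lists).
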