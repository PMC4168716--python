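# Methods

## Problem family and model

All problems act on a simple DAG *G* with *n* nodes and *m* edges, node
IDs opaque strings. A *cover* is a family of directed paths; a path may be
a single node (an isolated required node is otherwise uncoverable). The
constraint sets are: required nodes V′, required edges E′, subpath
constraints 𝒫<sup>in</sup> (each must appear contiguously in one solution
path), paired constraints (both members contiguously on the *same* path),
and, for the weighted problem, non-negative edge weights *w* and node sets
S ⊇ sources(G), T ⊇ sinks(G) where paths may start/end. "All nodes
required" is never implied; an instance with empty constraints has the
empty cover as its optimum (nothing forces a path).

Minimum weight is interpreted lexicographically: first the minimum number
of paths, then, among those, the minimum total edge weight with shared
edges counted once per use.

## Classical MPC by min-flow

Each node *v* becomes an arc (v<sub>in</sub>, v<sub>out</sub>) with flow
lower bound 1 iff *v* is required; edges become free arcs; a global source
feeds every source of *G* and every sink drains into a global sink. The
minimum feasible flow value equals the maximum antichain restricted to the
required set, and peeling unit paths off the flow yields the cover. The
min-flow is computed in two phases: a greedy feasible flow (one unit
routed through each unsaturated lower-bound arc), then a single max-flow
from sink to source on the residual network — implemented as a
shortest-augmenting-path loop at arc granularity, because residual graphs
of arc lists (with potential parallels) do not fit a simple digraph
container. Both phases are integral; correctness does not depend on the
asymptotically fastest max-flow choice at these instance sizes.

A Fulkerson-style construction (maximum bipartite matching on two copies
of V joined by transitive-closure edges, Hopcroft–Karp) is kept as an
independent engine and test oracle; closure edges expand to concrete paths
through recorded witness paths, chosen shortest-first with lexicographic
tie-breaks.

## Subpath constraints: the reduction pipeline

Stages, each recorded in a replayable trace:

1–2. *Normalization.* Endpoints of E′ edges leave V′; nodes/edges lying on
  a subpath constraint leave V′/E′ (a path covering the constraint covers
  them for free). Degenerate single-node subpaths are moved into V′ first;
  single-edge subpaths stay in the family (a shortcut edge for them is
  harmless after subdivision).
3. *Containment.* Constraints contained contiguously in another are
  dropped; duplicates keep their lowest index.
4. *Merging.* While any ordered pair (P, Q) has a suffix of P equal to a
  prefix of Q, the pair with the longest such overlap merges into one
  constraint (starting as P, ending as Q). Ties break by smallest first
  index, then smallest second index — the underlying argument only
  requires "longest possible", so the tie-break is a determinism choice.
  Overlap lengths are found by direct pairwise comparison, O(c²·ℓ); the
  optimal suffix-tree/all-pairs-overlap machinery has identical output and
  is deliberately not implemented at desk scale. After the loop, stage 3
  is re-run as a defensive assertion: the merge order provably creates no
  new containments, and a violation raises `MergeError` rather than being
  silently repaired (it would indicate corrupted state, and would be a
  finding worth surfacing).
5. *Shortcuts.* Each remaining subpath from s to t becomes a new edge
  (s, t), registered as an edge constraint; parallel edges are tolerated
  transiently.
6. *Subdivision.* Every edge constraint (original E′ edge or shortcut) is
  subdivided by a fresh required midpoint node, restoring simplicity.
  Midpoints remember whether they stand for an edge or a whole subpath.
7–8. *Closure and restriction* (unweighted path only). The transformed
  graph is replaced by its transitive closure (with witness paths), then
  induced on the required set. Classical MPC solves the result.

*Lifting* reverses the stages: closure edges expand through witnesses,
midpoints expand to their edge or full subpath (with boundary
deduplication), and the final paths are re-verified against the
**original** constraint sets — never the transformed ones — raising
`LiftError` on any discrepancy. In a DAG the expansions cannot revisit a
node (that would close a cycle), so lifted sequences are genuine paths.

The merge-free pipeline (stages 5–8 without 3–4) is exposed for testing
only; on the staggered-overlap fixture family it returns strictly more
paths than the oracle at every depth, which is exactly the failure mode of
reductions that ignore suffix/prefix-overlapping constraints.

## Weighted covers: min-cost circulation

After stages 1–6, coverage is a node requirement on the transformed graph,
and stages 7–8 are unnecessary: requirements become flow lower bounds.
Every node is split; the split arc carries lower bound 1 iff required.
Costs: original edges carry w(e); a subpath midpoint's split arc carries
the sum of its subpath's edge weights (its interior is bypassed by the
shortcut, so the cost rides on the midpoint); **a midpoint standing for an
original required edge e carries w(e)** — assigning it cost 0 would
silently drop w(e) from every cover using it, so this package prices it
explicitly; the two half-edges created by subdivision cost 0. The source
connects exactly to S, T exactly to the sink, and a return arc (t, s)
closes the circulation with cost equal to **one plus the sum of all arc
costs** — always, not only when all weights are zero: a path may cost
exactly the total, and strict dominance is what guarantees that every
min-cost circulation is simultaneously a minimum flow (lexicographic
optimality).

Lower bounds are removed by the standard demand transformation (bound ℓ on
(u, v) becomes demand +ℓ at u, −ℓ at v on a capacity-reduced arc); the
resulting ordinary min-cost flow is solved by network simplex on exact
rational costs (floats are read at their printed decimal value), so no
tolerance enters the optimization. Unbounded capacities are capped at one
more than the sum of all lower bounds, which no minimum circulation can
exceed. Because S ⊇ sources and T ⊇ sinks, every node of a DAG lies on
some S→T route; infeasibility can only arise from instances mutated past
validation, and is reported as `InfeasibleError`.

## Paired constraints: incompatibility coloring

Constraint atoms are required nodes (1-node subpaths), required edges
(2-node subpaths), single subpaths, and pairs (both members contributed).
Two atoms are *compatible* iff one directed path contains all contributed
subpaths contiguously, decided constructively: subpaths sharing nodes are
aligned and merged (conflicting alignments, or a shared node at two
offsets, mean no); the resulting disjoint segments must be totally
orderable by reachability from each segment's last node to the next's
first; the witness chains segments with deterministic shortest
connectors. In a DAG a connector cannot touch another segment without
closing a cycle, so the construction is complete, and the witness is
verified anyway.

Pairwise compatibility of a set implies joint realizability (the union of
the constraints has width 1), so the optimum is the chromatic number of
the incompatibility graph. `realize_class` still verifies its witness and
raises `RealizationError` on failure: a trigger would be a counterexample
to the pairwise-implies-joint property and must surface, not be guessed
around. OPT = 2 holds exactly when the incompatibility graph is bipartite
with at least one edge (edgeless means OPT ≤ 1; zero atoms mean OPT = 0).

The chromatic number is computed exactly by a maximum-clique lower bound
and greedy upper bound sandwiching DSATUR-style backtracking k-coloring
with the clique pre-colored for symmetry breaking. A subset-DP over
independent sets would also be exact, but is slower in pure Python at the
constraint counts the hardness gadgets produce (K4's gadget has 24 atoms);
branch-and-bound answers these in milliseconds. The FPT budget
(`max_classes`, default 20 constraints) bounds the accepted instance size;
exceeding it raises `LimitError` rather than degrading to a heuristic.

## Hardness gadget

The generator reverses 3-colorability into the paired-constraint problem.
For a non-bipartite source graph G (n vertices, m edges): a backbone
b₀ … b_{n+m+1}; per vertex v_k a block of three parallel length-2 branches
labeled v_k, X_k, Y_k; per edge e = {v_i, v_j} a block with branches
[v_i], [v_j] and one unlabeled; a tail edge after the last block. Pairs:
(v, [v]) for each second-stage label, and (v_k, tail), (X_k, tail),
(Y_k, tail) for every k — the tail device forces all three branches of
each first-stage block into the cover using paired constraints only.
Three paths then exist iff the vertex branches can be split into three
classes with no source edge inside one class, i.e. iff χ(G) = 3; the test
suite checks the biconditional on exhaustive 4-vertex and sampled 5-vertex
source graphs, and K4 (χ = 4) requires 4 paths. The original figure
accompanying the published reduction is not recoverable from text, so this
gadget is a reconstruction from the proof's stated properties; it has
width 3 (three parallel branches), whereas the published claim includes
width-2 series-parallel instances — that refinement is not reproduced.

## Synthetic data

`SimulationParams` defaults define the simulated locus: 20 pseudo-exons,
3 transcripts, per-exon inclusion probability 0.5 per transcript
(resampled below 2 exons; exons missed by all transcripts are inserted
into a random one, so the graph has no uncovered nodes), 10 long reads of
3 consecutive pseudo-exons, 5 read pairs with mate gaps of 1–3 exons.
Reads are windows of true transcripts, so every sampled constraint is
satisfiable and the constrained optimum never exceeds the transcript
count — which is what the recovery tests assert. The generator emulates
the combinatorial structure only: no sequencing errors, no coverage
noise, no mis-alignment, and no expression levels, so passing tests bound
solver correctness on clean constraint sets, not robustness to noisy real
reads. Graph, read and pair sampling use separate seeded RNG streams
(seed, seed+1, seed+2) so changing one sample size does not reshuffle the
others.

Test-scale choices: the Dilworth sweep enumerates all 2^{n(n−1)/2}
upper-triangular edge subsets per n ≤ 6 (every DAG is isomorphic to one;
the compared quantities are isomorphism-invariant) plus 200 random DAGs at
n = 25; brute-force oracles enumerate source-to-sink paths (any cover
extends to one of maximal paths without changing cardinality) up to 10
nodes; the gadget biconditional runs exhaustively on 4-vertex sources and
on a seeded sample of 5-vertex sources.

## Numerical and determinism choices

* All tie-breaking is lexicographic by node ID, then declaration order:
  topological orders, closure witnesses, BFS connectors, flow
  decomposition (smallest head first), merge-pair selection.
* Weighted optimization is exact rational arithmetic end to end; reported
  totals are floats only at the API surface.
* `max_antichain` beyond the enumeration limit uses a König vertex cover
  of the closure bipartite graph; the result is certificate-checked
  (genuine antichain, size n − |matching|), so optimality follows from
  weak duality rather than trust in the construction.
* Every public solver re-verifies its answer against the instance before
  returning (`verify_cover`); verification failures raise, they are never
  downgraded to warnings.

## Known limitations

* The FPT solver is exponential in the constraint count by nature; the
  default budget (20) is a safety valve, not a performance claim.
* Brute-force oracles are intentionally tiny-scale and raise `LimitError`
  beyond their budgets.
* The hardness gadget's width-2/series-parallel refinement is not
  reproduced (see above).
* Instance files are trusted JSON; there is no streaming parser for very
  large graphs, and dense transitive closures make the unweighted MPC-SC
  path quadratic in memory at large n.
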