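# Methods

## Model

A genome is a set of linear and circular chromosomes over signed
syntenic blocks ("genes"); each gene contributes a tail and a head
extremity, and a genome is equivalently its multiset of adjacencies
(internal: unordered extremity pairs; external: a single extremity at a
linear chromosome end). A DCJ cuts one or two adjacencies and rejoins
the ends in one of four ways: {a,b},{c,d}→{a,c},{b,d};
{a,b},{c}→{a,c},{b}; {a,b}→{a},{b}; {a},{b}→{a,b}.

The breakpoint graph G(A, B) has a vertex per extremity plus the
chromosome-endpoint vertex `o`; black edges are A's adjacencies
(external {a} becomes {a, o}), gray edges B's, and monochromatic
`o`-loops raise both color degrees at `o` to 2n. With this balancing, a
DCJ on A — including fissions and fusions, which consume or produce a
black loop — is exactly a 2-break on the black edges, and the minimum
scenario length is d2b = e − c with c the MAECD size. Loop bookkeeping
is immaterial for distances: adding a black/gray loop pair raises e and
c by one each (asserted as a property test), so the Definition-style
count (degree 2n, used for reported e and c) and a minimal balancing
count (used where cycle enumeration should stay small) give the same
d2b.

Cost constraints are expressed on labeled graphs: a labeling λ assigns a
label to every vertex and edge, an operation set 𝒪 contains edge-label
changes (({a,b},x);({a,b},y)) and 2-breaks on labels
(({a,b},x),({c,d},y);({a,c},z),({b,d},t)), and φ: 𝒪 → ℝ₊ prices each
member. An 𝒪-scenario must end in a terminal graph whose black and gray
*labeled* edge multisets agree. MCPS_φ is the minimum cost over
𝒪-scenarios whose 2-break count equals d2b; if 𝒪 cannot realize any
such scenario (𝒪 is not p-sufficient for the instance), the value is ∞,
and the solvers report it as such rather than relaxing parsimony.

Operation sets are intensional predicates — the intergene-length set is
infinite — with constant-time membership. Built-in models:

| model | Σ_E | 2-break members | 2-break cost | change members | change cost |
|---|---|---|---|---|---|
| `model_phi_f(Φ, τ)` | Σ ∪ {τ} | label-preserving, x,y ∈ Σ | Φ(x,y) | x → τ | 0 |
| `model_hic` | intervals ∪ {τ} | as φ_f | Φmax − Φ_HiC(x,y) | x → τ | 0 |
| `model_phi_l()` | ℕ | w1+w2 = w3+w4 | 0 | any w1 → w2 | \|w1−w2\| |
| `model_vertex(f)` | {τ} | all | f(a,b,c,d) on vertex labels | none | — |

Two conventions are worth making explicit. First, φ_f 2-breaks are
members only for labels in Σ (the cost table's index): a black edge
labeled τ cannot break, so an instance that forces a fission through a
τ-labeled black `o`-loop has MCPS = ∞ under φ_f — honestly, and
identically in the exact pipeline and the brute-force oracle. Users who
want feasible fissions give loops a Σ color (`--loop-label` in the CLI;
the synthetic generator labels every black edge from Σ). Second, the
φ_f label change x → τ is defined on any edge, so the terminal
relabeling may touch gray edges as well; for genome instances gray
labels are already τ and this is a no-op.

## Algorithms

**Circles (fixed labels).** For a labeled circle with r black edges,
every parsimonious 𝒪-scenario induces a graph T(ρ) on the circularly
embedded black-edge labels — one edge {x, y} per 2-break — and T(ρ) is a
non-crossing ("planar") spanning tree of cost equal to the scenario's;
conversely every planar tree is realized by a scenario. MCPS is
therefore the minimum-cost planar tree, found by the interval dynamic
program

    cost(i,j) = min over i ≤ s < q ≤ j of
                cost(i,s) + cost(s+1,q) + cost(q,j) + Φ(i,q),

with cost(i,i) = 0. The implementation factors the inner minimum over s
into M(i,q) = min_s cost(i,s) + cost(s+1,q), filling the table in
O(r³) instead of the textbook O(r⁴); the optimum is unchanged and is
cross-checked against an exhaustive enumeration of non-crossing spanning
trees up to r = 6. Duplicate labels need no special handling because
the table is indexed by position (the formal treatment replaces a
repeated label by a fresh one with a copied table row). Scenario
extraction repeatedly picks a tree edge joining two adjacent positions
with at least one tree-leaf endpoint — a planar tree always has such a
"short edge incident to a leaf" — emits the 2-break that detaches a
terminal black/gray pair carrying the leaf's label, and shrinks the
circle; r − 1 breaks realize exactly the tree's edges, then free label
changes reach the labeled-terminal state.

**Simple cycles.** A simple cycle S (c = 1) has color degrees ≤ 2
everywhere; splitting a degree-two vertex v into v1, v2 yields one graph
when v carries a monochromatic loop (the loop becomes the edge {v1,v2})
and two graphs otherwise (the two alternation-preserving dart pairings),
all simple cycles. Iterating over all deg₂(S) such vertices gives the
set circ(S) of at most 2^deg₂ circles, and MCPS(S) is the minimum over
circ(S). Splitting preserves edge ids and dart slots, so the winning
circle's scenario replays verbatim on S.

**Breakpoint graphs.** Every non-`o` vertex has color degrees 1/1, so
circles of G(A,B) are forced parts of every MAECD. What remains is a
union of alternating paths between visits of `o`: paths with
differently colored end edges close through `o` into circles; AA paths
(black ends) must pair with BB paths (gray ends), each union being a
simple cycle with deg₂ = 1 — hence at most two circles after one split.
When telomere counts differ the AA and BB counts differ too; black
`o`-loops act as pseudo-AA elements and gray loops as pseudo-BB
elements (an AA path closed by a gray loop is a simple cycle, a loop
pair is a 1-edge circle), which always equalizes the two sides of the
complete bipartite graph H. A minimum-weight perfect matching of H
(scipy's Hungarian implementation) with simple-cycle MCPS weights
finishes the assembly; identically labeled loops share cached weights,
and the chosen pairs are re-solved on their actual edges so the merged
scenario references the right edge ids. With an O(r^t) circle solver
the whole pipeline is O(n^{t+1}) in the worst case and O(m·n^t) with m
chromosomes in practice, the matching being the bottleneck only when
the path count is large.

**α-approximation.** The same assembly run with an α-approximate circle
solver is an α-approximation overall: minima and sums of α-approximate
values stay α-approximate. The bundled `ApproximateCircleSolver` is a
synthetic test harness for this wrapper — it deterministically prefers
the "path" planar tree when that stays within α of the optimum, so its
inflated value is still the true cost of the scenario it returns.

**General graphs.** When vertices may have color degrees 2/2 (duplicated
genes), MAECD is NP-hard and the package enumerates all simple cycles
(closed alternating trails without a proper balanced sub-trail, found by
dart-level DFS) and solves two 0/1 ILPs with scipy's HiGHS `milp`:
maximize the number of edge-disjoint simple cycles (= c(G)), then
minimize the summed simple-cycle MCPS subject to edge-disjointness and
that cardinality. The packing constraints are inequalities, but a
maximum packing of an Eulerian graph necessarily covers it (the
uncovered remainder would be balanced and would decompose into further
cycles), so the selected cycles always form a decomposition — this is
asserted at run time. Infinite-cost cycles are excluded from the second
ILP by fixing their variables to zero; infeasibility then reports ∞.

**Brute-force oracle.** An independent check at small sizes (≤ 6–8
black edges): memoized depth-first search over all 2-breaks that lower
the remaining distance by one, each with every member product labeling
(`break_options`), settling labels once the graph is terminal. Label
changes are only explored at the end because every built-in model lets a
mid-scenario change be deferred at equal cost: φ_f changes are free but
only retarget τ (and a τ edge can no longer break, so changing early
never helps); φ_l 2-breaks redistribute label mass freely among the
products, so a mid-scenario indel of |δ| can be pushed through the
remaining breaks and applied at the end for the same |δ|; the vertex
model has no changes. The oracle shares nothing with the planar-tree /
matching pipeline beyond the graph data structures.

**Scenario decomposition.** The trajectory graph D(G, ρ) starts with a
2-vertex arc per black edge; each 2-break merges the head vertices of
its operand arcs and sprouts two fresh arcs. Its weakly connected
components partition ρ into independent subscenarios and G into
edge-disjoint Eulerian subgraphs, k ≥ e − m of them; for parsimonious ρ,
k = c(G) and the subgraphs form a MAECD of simple cycles. This is both
a structural test target and the justification for solving cycle by
cycle.

## Numerical and representational choices

* **Darts.** Edges have two distinguishable endpoints ("darts"), so
  2-breaks on parallel edges and on loops are unambiguous; a 2-break is
  recorded as (e1, s1, e2, s2) at dart level and pretty-printed as edge
  pairs.
* **Scenario ids.** Product edges of a recorded step carry
  scenario-local ids; replay translates them to actually allocated ids,
  which keeps a scenario valid when independent subscenarios are
  concatenated in any order.
* **Ties.** The planar-tree DP breaks ties by first optimum in a fixed
  scan order (deterministic, reproducible across runs; not necessarily
  the lexicographically smallest edge set). The Hungarian matching and
  the ILP backend are deterministic for fixed inputs.
* **Floats.** Costs are float sums of table entries; oracle-vs-pipeline
  comparisons in tests use absolute tolerance 1e-9. Infinite values are
  IEEE inf; the matching replaces inf by a finite sentinel larger than
  any feasible total and rejects assignments that use it.
* **Degenerate inputs.** Empty genomes, single-gene circles (adjacency
  {head, tail}), r = 1 circles (no 2-breaks, label settling only), and
  terminal inputs (empty scenario) are all handled and tested.
* **Canonical genome form.** Linear chromosomes are oriented by a
  deterministic key on (|gene|, sign); circular ones additionally choose
  the minimal rotation. Genome reconstruction from adjacencies is exact
  for single-copy genomes; with duplicated genes the chromosome
  structure can be ambiguous, a greedy traversal is used, and the result
  is verified against the input adjacencies (an error is raised on
  inconsistency).

## Synthetic data

Generators are pure functions of (configuration, seed), built on
numpy's PCG64. `random_genome` draws a uniform signed permutation split
at uniform cut points; `scramble` applies k valid DCJs drawn uniformly
over the applicable rewrite forms (form weights are a configuration
knob), so d2b ≤ k by construction; `random_phi` draws a symmetric
uniform table; `random_instance` assembles a labeled breakpoint graph
whose black edges — `o`-loops included — carry uniform colors from the
alphabet, which keeps the fixed-label operation set p-sufficient. The
default study conditions are small (2–3 genes, 1–2 chromosomes, 2–5
scramble moves, ≤ 5 colors, Φ ~ U(0,1)) because that is the regime in
which the exhaustive oracle can certify every answer; the large-scale
smoke test (100 genes, 4 chromosomes, 60 moves) exercises the
polynomial pipeline end to end with certificate validation.

What the generator does not emulate: real syntenic-block inference,
chromosome-number drift, rearrangement rate heterogeneity, realistic
Hi-C maps, or gene duplication dynamics (the duplicated-gene path is
exercised by a fixed worked-example fixture instead). Passing tests
therefore certify the combinatorics and optimality of the algorithms,
not the biological fidelity of any particular cost table.

Two exhaustive universes back the desk-scale checks: all simple
alternating cycles with exactly two degree-two vertices and at most 8
black edges (enumerated as canonical closed alternating walks with
exactly two repeated vertices, deduplicated up to rotation, reflection
and relabeling), and all genome pairs on up to 3 single-copy genes
(first genome reduced to orbit representatives under simultaneous gene
renaming/flipping, which leaves the breakpoint graph unchanged).

## Known limitations

* MAECD and hence `d2b` on graphs that are neither breakpoint-shaped
  nor small is out of reach (NP-hard); the exhaustive oracle refuses
  more than 8 black edges and the ILP route needs the simple cycles to
  be enumerable.
* There is no polynomial listing of simple cycles of a 2-edge-colored
  graph; `enumerate_simple_cycles` is exponential and guarded by a
  limit.
* The specialized O(r log r) circle algorithm for the intergene-length
  model is not reimplemented (it lives in its own publication);
  `BruteForceCircleSolver` fills that registry slot exactly at small
  scale, and a faster implementation can be plugged in unchanged to get
  the O(n³) assembled behavior.
* Minimum-cost scenarios *without* the parsimony constraint are a
  different (NP-hard) problem and are not computed here; scenario
  counting and sampling are likewise out of scope.
* φ_f instances whose gray edges carry labels outside Σ ∪ {τ} can be
  validated but not always settled; the solvers report ∞ when the
  labeled-terminal state is unreachable with member changes.
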