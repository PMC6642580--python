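# mcps — minimum-cost parsimonious rearrangement scenarios

`mcps` computes genome rearrangement scenarios under the double cut and
join (DCJ) model that are simultaneously *parsimonious* (of minimum
length) and *of minimum cost* under a biologically motivated weighting
of the individual operations.

## The problem

Two genomes A and B over the same syntenic blocks are compared through
their breakpoint graph G(A, B): one vertex per block extremity plus a
chromosome-endpoint vertex `o`, a black edge for every adjacency of A, a
gray edge for every adjacency of B, and enough `o`-loops that both color
degrees at `o` equal 2n. A DCJ on A is a *2-break* on this graph — two
black edges {x1,x2}, {x3,x4} are replaced by {x1,x3},{x2,x4} or
{x1,x4},{x2,x3} — and sorting A into B means rewiring the black edges
onto the gray ones. The minimum number of 2-breaks is

    d2b(G) = e(G) − c(G),

where e(G) counts black edges and c(G) is the size of a maximum
alternating edge-disjoint cycle decomposition (MAECD).

Not all shortest scenarios are equally plausible. Edges and vertices of
the graph carry labels (spatial "colors" of intergenic regions, Hi-C
contact intervals, intergene lengths in nucleotides, genomic
coordinates), an operation set 𝒪 says which label-aware 2-breaks and
edge-label changes are allowed, and a cost function φ prices each
operation. The *minimum cost parsimonious scenario* value MCPS_φ(G, λ)
is the cheapest total cost among 𝒪-scenarios using exactly d2b(G)
2-breaks (∞ when none exists).

## What the package computes

* **Exact circle solver.** On a labeled *circle* with fixed labels
  (cost Φ(x, y) for a 2-break acting on labels x and y, relabeling to
  the terminal label τ free), parsimonious scenarios correspond to
  non-crossing (planar) spanning trees over the circularly ordered
  black-edge labels, with equal cost. A dynamic program over circular
  intervals finds the minimum-cost planar tree, and the tree is unfolded
  back into an explicit scenario certificate.
* **Simple cycles.** A simple alternating cycle (c = 1) that is not a
  circle is reduced by splitting its degree-two vertices; the answer is
  the minimum over the at most 2^deg₂ resulting circles.
* **Breakpoint graphs.** Circles of G(A, B) are forced parts of every
  MAECD; the remaining AA/BB paths (and `o`-loops, which act as
  zero-length pseudo-paths) are paired by a minimum-weight perfect
  matching (Hungarian algorithm) whose edge weights are simple-cycle
  MCPS values. Any circle solver — exact, specialized, or
  α-approximate — plugs into this assembly; an α-approximate circle
  solver yields an α-approximate total.
* **General graphs** (e.g. duplicated genes): two set-packing ILPs over
  the enumerated simple cycles — maximize the cycle count, then minimize
  total cycle cost at that count (solved with scipy's HiGHS backend).
* **Built-in cost models**: fixed colors (`model_phi_f`, including the
  0/1 indicator model), Hi-C weights (`model_hic`, cost Φmax − Φ_HiC),
  intergene lengths with indels (`model_phi_l`, sum-conserving free
  2-breaks, indels cost |δ|), and vertex-based costs (`model_vertex`).
* **Scenario machinery**: DCJ ↔ 2-break translation, ghost adjacencies
  for unequal gene content, trajectory-graph decomposition of a scenario
  into independent subscenarios, validation and costing of any scenario
  file, and a brute-force oracle for small instances.

## Worked example

The genome pair A = (1 2 −3), B = (1 −2 −3) on one linear chromosome:

```python
from mcps import (Genome, build_breakpoint_graph, decompose_breakpoint_graph,
                  PhiMatrix, model_phi_f, solve_breakpoint_graph,
                  validate_and_cost, LabeledGraph, Labeling,
                  PlanarTreeCircleSolver)

A = Genome.from_orders([1, 2, -3], name="A")
B = Genome.from_orders([1, -2, -3], name="B")
bg = build_breakpoint_graph(A, B)
dec = decompose_breakpoint_graph(bg.graph)
print("e =", bg.graph.e(), " c =", dec.c, " d2b =", bg.graph.e() - dec.c)
```

prints `e = 6  c = 5  d2b = 1`: the breakpoint graph has six black edges
(four adjacencies plus two balancing `o`-loops) and a maximum
decomposition into five alternating cycles, so one DCJ sorts A into B —
the reversal of block 2. Coloring A's adjacencies (`1t`,`1h-2t` red,
`2h-3h`,`3t` blue) and pricing 2-breaks with a symmetric table Φ:

```python
phi = PhiMatrix.from_dict({("red", "red"): 0.2, ("red", "blue"): 1.0,
                           ("blue", "blue"): 0.5})
model = model_phi_f(phi)
# ... label the black edges, then:
res = solve_breakpoint_graph(gl, PlanarTreeCircleSolver(model))
cost, breaks = validate_and_cost(gl, res.scenario, model)
```

prints `MCPS = 1.0` realized by `1` 2-break: the single sorting DCJ cuts
one red and one blue region, so the cheapest parsimonious scenario costs
Φ(red, blue) = 1. The returned scenario is a step-by-step certificate
that `validate_and_cost` replays and re-prices independently.

The same computation from the shell:

```sh
$ mcps distance A.txt B.txt
n = 3
e = 6
c = 5
d2b = 1
$ mcps solve --model phi --genomes A.txt B.txt \
    --labels labels.tsv --phi phi.tsv --loop-label red --out s.jsonl
d2b = 1
MCPS = 1
```

`mcps simulate`, `mcps tree`, `mcps graph-info` and `mcps validate`
cover data generation, the planar-tree certificate, graph inspection and
scenario re-validation; `--help` on any subcommand lists the options.

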