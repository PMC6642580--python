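"""2-break scenarios, the e - c distance, and trajectory decomposition.

A 2-break replaces two black edges {x1,x2}, {x3,x4} by {x1,x3},{x2,x4}
or {x1,x4},{x2,x3}.  The minimum number of 2-breaks transforming a graph
into a terminal one is e(G) - c(G), where e is the black edge count and
c the size of a maximum alternating edge-disjoint cycle decomposition.
For genomes, a parsimonious 2-break scenario on the breakpoint graph
translates step for step into a parsimonious DCJ scenario.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import networkx as nx

from .genomes import Adjacency, DcjOperation, Genome, adjacencies_of, genome_from_adjacencies
from .colored_graphs import (
    BLACK,
    GRAY,
    TELOMERE,
    BreakpointGraph,
    ColoredGraph,
    alternating_circuit,
    decompose_breakpoint_graph,
    is_breakpoint_shaped,
    is_terminal,
    maecd_exhaustive,
)

__all__ = [
    "TwoBreak",
    "TrajectoryGraph",
    "apply_two_break",
    "apply_scenario",
    "c_of",
    "d2b",
    "structural_maecd",
    "parsimonious_scenario",
    "cycle_scenario",
    "trajectory",
    "decompose_scenario",
    "two_break_scenario_to_dcj",
]


@dataclass(frozen=True)
class TwoBreak:
    """A 2-break given at dart level.

    Operand black edges ``e1``, ``e2`` are replaced by the two edges
    pairing dart ``(e1, s1)`` with ``(e2, s2)`` and ``(e1, 1-s1)`` with
    ``(e2, 1-s2)``.  The dart-level record keeps 2-breaks on loops and on
    parallel edges unambiguous; the two pairings of the definition are
    ``s2`` and ``1 - s2`` for a fixed ``s1``.

    ``p1``/``p2`` optionally declare scenario-local ids for the two
    product edges so that later steps can reference them; replay maps
    them to the actually allocated ids, which keeps a scenario valid
    under reordering of its independent subscenarios.
    """

    e1: int
    e2: int
    s1: int = 0
    s2: int = 0
    p1: int | None = None
    p2: int | None = None

    def __post_init__(self) -> None:
        if self.e1 == self.e2:
            raise ValueError("a 2-break needs two distinct black edges")
        if self.s1 not in (0, 1) or self.s2 not in (0, 1):
            raise ValueError("dart sides are 0 or 1")

    @property
    def inverse_sides(self) -> "TwoBreak":
        return TwoBreak(self.e1, self.e2, self.s1, 1 - self.s2)


def _resolved(tb: TwoBreak, real: dict[int, int]) -> TwoBreak:
    return TwoBreak(real.get(tb.e1, tb.e1), real.get(tb.e2, tb.e2), tb.s1, tb.s2)


def apply_two_break(g: ColoredGraph, tb: TwoBreak) -> tuple[ColoredGraph, tuple[int, int]]:
    """Apply a 2-break; returns the new graph and the two new edge ids.

    The first new edge joins ``(e1, s1)`` to ``(e2, s2)``; gray edges are
    untouched, so Eulerian-ness is preserved.
    """
    for eid in (tb.e1, tb.e2):
        if eid not in g.edges:
            raise ValueError(f"operand edge {eid} absent")
        if g.edges[eid].color != BLACK:
            raise ValueError(f"operand edge {eid} is not black")
    e1, e2 = g.edges[tb.e1], g.edges[tb.e2]
    g2 = g.copy()
    g2.remove_edge(tb.e1)
    g2.remove_edge(tb.e2)
    f1 = g2.add_edge(BLACK, e1.endpoint(tb.s1), e2.endpoint(tb.s2))
    f2 = g2.add_edge(BLACK, e1.endpoint(1 - tb.s1), e2.endpoint(1 - tb.s2))
    return g2, (f1, f2)


def apply_scenario(g: ColoredGraph, rho: list[TwoBreak]) -> ColoredGraph:
    real: dict[int, int] = {}
    for tb in rho:
        g, (f1, f2) = apply_two_break(g, _resolved(tb, real))
        if tb.p1 is not None:
            real[tb.p1] = f1
            real[tb.p2] = f2
    return g


def structural_maecd(g: ColoredGraph) -> list[frozenset]:
    """A MAECD of a breakpoint-shaped graph, from its path decomposition.

    Circles are forced parts; AA/BB paths and o-loops are paired off
    deterministically (all pairings give decompositions of the same,
    maximum, cardinality).
    """
    dec = decompose_breakpoint_graph(g)
    parts = [frozenset(c) for c in dec.circles]
    lefts = [frozenset(dec.aa_paths[x]) if kind == "path" else frozenset([x]) for kind, x in dec.left]
    rights = [frozenset(dec.bb_paths[x]) if kind == "path" else frozenset([x]) for kind, x in dec.right]
    if len(lefts) != len(rights):
        raise ValueError("graph is not Eulerian at o")
    parts.extend(l | r for l, r in zip(lefts, rights))
    return parts


def c_of(g: ColoredGraph, c: int | None = None, limit: int = 8) -> int:
    """c(G), structurally for breakpoint-shaped graphs, else exhaustively."""
    if c is not None:
        return c
    if is_breakpoint_shaped(g):
        return decompose_breakpoint_graph(g).c
    return len(maecd_exhaustive(g, limit))


def d2b(g: ColoredGraph, c: int | None = None, limit: int = 8) -> int:
    """Minimum length of a 2-break scenario: e(G) - c(G)."""
    return g.e() - c_of(g, c, limit)


def cycle_scenario(g: ColoredGraph, cycle_edges) -> tuple[ColoredGraph, list[TwoBreak]]:
    """Parsimonious 2-breaks sorting one alternating cycle of ``g``.

    Walks the cycle's alternating circuit b1 g1 b2 g2 ... and repeatedly
    replaces b1, b2 by the edge parallel to g1 plus a shorter chord,
    peeling off one terminal pair per step.  Returns the transformed
    graph and the steps (length = #black edges - 1).
    """
    circuit = alternating_circuit(g, cycle_edges)
    steps: list[TwoBreak] = []
    # circuit alternates black/gray starting with black
    walk = list(circuit)
    while len(walk) > 2:
        (b1, s1), (g1, _), (b2, s2) = walk[0], walk[1], walk[2]
        # b1 entered at side s1 so its exit dart is (b1, 1-s1); b2 is
        # entered at (b2, s2).  Pairing those two darts creates the edge
        # parallel to the gray edge g1 between them.
        tb = TwoBreak(b1, b2, 1 - s1, s2, g._next_id, g._next_id + 1)
        g, (f1, f2) = apply_two_break(g, tb)
        assert (f1, f2) == (tb.p1, tb.p2)
        steps.append(tb)
        # f2 joins b1's entry endpoint to b2's exit endpoint; the new
        # walk enters f2 at b1's old entry dart (side 0 of f2).
        walk = [(f2, 0)] + walk[3:]
    return g, steps


def parsimonious_scenario(
    g: ColoredGraph,
    decomposition: list[frozenset] | None = None,
    limit: int = 8,
) -> list[TwoBreak]:
    """A minimum-length 2-break scenario (length e - c) making g terminal."""
    if decomposition is None:
        decomposition = structural_maecd(g) if is_breakpoint_shaped(g) else maecd_exhaustive(g, limit)
    steps: list[TwoBreak] = []
    current = g
    for part in sorted(decomposition, key=sorted):
        current, sub = cycle_scenario(current, part)
        steps.extend(sub)
    if not is_terminal(current):
        raise AssertionError("scenario did not reach a terminal graph")
    return steps


# ---------------------------------------------------------------------------
# Trajectory graph D(G, rho)
# ---------------------------------------------------------------------------

class _DSU:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        p = self.parent.setdefault(x, x)
        if p != x:
            self.parent[x] = p = self.find(p)
        return p

    def union(self, x, y) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


@dataclass
class TrajectoryGraph:
    """The directed history graph of a scenario.

    One arc per (intermediate) black edge; each 2-break merges the head
    vertices of its two operand arcs and grows two fresh arcs from the
    merged vertex.  Weak connectivity of the final graph partitions the
    scenario into independent subscenarios.
    """

    digraph: nx.MultiDiGraph
    initial_edges: list[int]
    edge_component: dict[int, int]  # arc label (edge id) -> component index
    step_component: list[int]

    @property
    def n_components(self) -> int:
        return nx.number_weakly_connected_components(self.digraph)


def trajectory(g: ColoredGraph, rho: list[TwoBreak]) -> TrajectoryGraph:
    dsu = _DSU()
    arcs: list[tuple[object, object, int]] = []  # (tail node, head node, black edge id)
    initial = g.black_ids()
    for eid in initial:
        arcs.append((("tail", eid), ("head", eid), eid))

    current = g
    real: dict[int, int] = {}
    merged_of_step: list[object] = []
    for tb in rho:
        res = _resolved(tb, real)
        h1, h2 = ("head", res.e1), ("head", res.e2)
        dsu.union(h1, h2)
        current, (f1, f2) = apply_two_break(current, res)
        if tb.p1 is not None:
            real[tb.p1] = f1
            real[tb.p2] = f2
        arcs.append((h1, ("head", f1), f1))
        arcs.append((h1, ("head", f2), f2))
        merged_of_step.append(h1)

    dg = nx.MultiDiGraph()
    for t, h, label in arcs:
        dg.add_edge(dsu.find(t), dsu.find(h), label=label)
    comp_index: dict = {}
    for i, comp in enumerate(sorted(nx.weakly_connected_components(dg), key=lambda c: sorted(map(str, c)))):
        for node in comp:
            comp_index[node] = i
    edge_component = {label: comp_index[dsu.find(t)] for t, h, label in arcs}
    step_component = [comp_index[dsu.find(m)] for m in merged_of_step]
    return TrajectoryGraph(dg, initial, edge_component, step_component)


def decompose_scenario(
    g: ColoredGraph, rho: list[TwoBreak]
) -> list[tuple[ColoredGraph, list[TwoBreak]]]:
    """Partition a scenario into independent subscenarios (one per
    trajectory-graph component) together with the Eulerian subgraphs they
    sort.  For a parsimonious scenario the subgraphs form a MAECD and are
    all simple cycles.
    """
    final = apply_scenario(g, rho)
    if not is_terminal(final):
        raise ValueError("rho is not a scenario: final graph is not terminal")
    traj = trajectory(g, rho)
    k = traj.n_components

    # Black edges of each part: initial arcs by component.
    black_parts: dict[int, list[int]] = defaultdict(list)
    for eid in traj.initial_edges:
        black_parts[traj.edge_component[eid]].append(eid)

    # Gray edges: final black edges (arcs into sinks) matched to gray edge
    # ids of g by endpoint multiset, per component.
    final_black: dict[int, list[int]] = defaultdict(list)
    for eid in final.black_ids():
        final_black[traj.edge_component[eid]].append(eid)

    gray_pool: dict[tuple, list[int]] = defaultdict(list)
    for eid in sorted(g.edges):
        e = g.edges[eid]
        if e.color == GRAY:
            gray_pool[e.pair()].append(eid)

    parts: list[tuple[ColoredGraph, list[TwoBreak]]] = []
    for comp in range(k):
        edge_ids = list(black_parts[comp])
        for feid in sorted(final_black[comp]):
            pair = final.edges[feid].pair()
            edge_ids.append(gray_pool[pair].pop())
        sub = g.subgraph(edge_ids)
        sub_rho = [tb for tb, c in zip(rho, traj.step_component) if c == comp]
        parts.append((sub, sub_rho))
    return parts


# ---------------------------------------------------------------------------
# Translation to DCJ scenarios on genomes
# ---------------------------------------------------------------------------

def _edge_to_adjacency(e) -> Adjacency | None:
    if e.u == TELOMERE and e.v == TELOMERE:
        return None
    if e.u == TELOMERE:
        return Adjacency.external(e.v)
    if e.v == TELOMERE:
        return Adjacency.external(e.u)
    return Adjacency.internal(e.u, e.v)


def two_break_scenario_to_dcj(
    a: Genome, b: Genome, rho: list[TwoBreak], bg: BreakpointGraph | None = None
) -> list[DcjOperation]:
    """Translate a 2-break scenario on G(A, B) into a DCJ scenario on A.

    ``rho`` must be a scenario for the Definition-2 breakpoint graph of
    (A, B) (pass the graph it was computed on as ``bg`` to reuse edge
    ids).  A 2-break consuming a black o-loop is a chromosome fission;
    one producing an o-loop is a fusion; a 2-break touching only o-loops
    is a genome no-op and is rejected.
    """
    from .colored_graphs import build_breakpoint_graph

    if bg is None:
        bg = build_breakpoint_graph(a, b)
    g = bg.graph
    ops: list[DcjOperation] = []
    genome = a
    real: dict[int, int] = {}
    for tb in rho:
        res = _resolved(tb, real)
        e1, e2 = g.edges[res.e1], g.edges[res.e2]
        consumed = [adj for adj in (_edge_to_adjacency(e1), _edge_to_adjacency(e2)) if adj is not None]
        if not consumed:
            raise ValueError("2-break touching only o-loops is a genome no-op")
        g, (f1, f2) = apply_two_break(g, res)
        if tb.p1 is not None:
            real[tb.p1] = f1
            real[tb.p2] = f2
        produced = [
            adj for adj in (_edge_to_adjacency(g.edges[f1]), _edge_to_adjacency(g.edges[f2])) if adj is not None
        ]
        op = DcjOperation(tuple(consumed), tuple(produced))
        genome = genome_from_adjacencies(
            _rewrite(adjacencies_of(genome), op), genome.gene_multiset, genome.name
        )
        ops.append(op)
    if not genome.same_as(b):
        raise AssertionError("translated DCJ scenario does not reach genome B")
    return ops


def _rewrite(adjs: Counter, op: DcjOperation) -> Counter:
    need = Counter(op.consumed)
    for adj, mult in need.items():
        if adjs[adj] < mult:
            raise ValueError(f"adjacency {adj} not present")
    adjs = adjs - need
    adjs.update(op.produced)
    return adjs
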