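"""Eulerian 2-edge-colored multigraphs and breakpoint graphs.

The central object is a multigraph whose edges are colored black or gray:
black edges carry the adjacencies of the source genome, gray edges those
of the target.  A graph is *Eulerian* when every vertex has equal black
and gray degree, *terminal* when the black and gray edge multisets agree.
Sorting one genome into the other is rewiring the black edges onto the
gray ones by 2-breaks.

Alternating cycles, the maximum alternating edge-disjoint cycle
decomposition (MAECD, whose size is c(G)), simple cycles (c = 1) and
circles (simple cycles visiting no vertex twice) are all defined here,
together with the degree-two vertex splitting that reduces a simple
cycle to a set of circles.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .genomes import Extremity, Genome, adjacencies_of, complete_gene_content

__all__ = [
    "TELOMERE",
    "BLACK",
    "GRAY",
    "Edge",
    "ColoredGraph",
    "Labeling",
    "LabeledGraph",
    "BreakpointGraph",
    "PathDecomposition",
    "build_breakpoint_graph",
    "breakpoint_graph_from_adjacencies",
    "is_terminal",
    "is_breakpoint_shaped",
    "decompose_breakpoint_graph",
    "alternating_circuit",
    "closed_alternating_trails",
    "is_simple_cycle",
    "maecd_exhaustive",
    "enumerate_simple_cycles",
    "split_degree_two_vertex",
    "circ",
    "read_edge_list",
    "write_edge_list",
]

TELOMERE = "o"  # the chromosome-endpoint vertex, printed as 'o'
BLACK = "black"
GRAY = "gray"
TAU = "tau"  # conventional terminal edge label


def _vk(v) -> str:
    """Total, deterministic order over heterogeneous vertex identifiers."""
    return str(v)


@dataclass(frozen=True)
class Edge:
    color: str
    u: object
    v: object

    @property
    def is_loop(self) -> bool:
        return self.u == self.v

    def endpoint(self, side: int):
        return self.u if side == 0 else self.v

    def pair(self) -> tuple:
        return tuple(sorted((self.u, self.v), key=_vk))


class ColoredGraph:
    """Undirected 2-edge-colored multigraph with identified edges.

    Every edge has an integer id and two *darts* ``(edge_id, 0)`` and
    ``(edge_id, 1)`` (one per endpoint; a loop's darts share a vertex but
    stay distinguishable), which is what makes 2-breaks on parallel edges
    and on loops unambiguous.
    """

    def __init__(self) -> None:
        self.edges: dict[int, Edge] = {}
        self._next_id = 0

    # -- construction -------------------------------------------------
    def add_edge(self, color: str, u, v, eid: int | None = None) -> int:
        if color not in (BLACK, GRAY):
            raise ValueError(f"color must be {BLACK!r} or {GRAY!r}")
        if eid is None:
            eid = self._next_id
        if eid in self.edges:
            raise ValueError(f"edge id {eid} already used")
        self.edges[eid] = Edge(color, u, v)
        self._next_id = max(self._next_id, eid + 1)
        return eid

    def remove_edge(self, eid: int) -> Edge:
        return self.edges.pop(eid)

    def new_id(self) -> int:
        eid = self._next_id
        self._next_id += 1
        return eid

    def copy(self) -> "ColoredGraph":
        g = ColoredGraph()
        g.edges = dict(self.edges)
        g._next_id = self._next_id
        return g

    def subgraph(self, edge_ids) -> "ColoredGraph":
        g = ColoredGraph()
        for eid in edge_ids:
            g.edges[eid] = self.edges[eid]
        g._next_id = self._next_id
        return g

    # -- queries -------------------------------------------------------
    def vertices(self) -> set:
        vs = set()
        for e in self.edges.values():
            vs.add(e.u)
            vs.add(e.v)
        return vs

    def degree(self, v, color: str) -> int:
        d = 0
        for e in self.edges.values():
            if e.color != color:
                continue
            d += (e.u == v) + (e.v == v)
        return d

    def edge_ids(self, color: str | None = None) -> list[int]:
        return sorted(eid for eid, e in self.edges.items() if color is None or e.color == color)

    def black_ids(self) -> list[int]:
        return self.edge_ids(BLACK)

    def e(self) -> int:
        """Number of black edges (the e(G) of the minimum-length formula)."""
        return sum(1 for e in self.edges.values() if e.color == BLACK)

    def is_eulerian(self) -> bool:
        bal: dict = defaultdict(int)
        for e in self.edges.values():
            sgn = 1 if e.color == BLACK else -1
            bal[e.u] += sgn
            bal[e.v] += sgn
        return all(x == 0 for x in bal.values())

    def incident(self, v, color: str | None = None) -> list[tuple[int, int]]:
        """Darts at v: sorted list of (edge_id, side)."""
        darts = []
        for eid in sorted(self.edges):
            e = self.edges[eid]
            if color is not None and e.color != color:
                continue
            if e.u == v:
                darts.append((eid, 0))
            if e.v == v:
                darts.append((eid, 1))
        return darts

    def canonical_form(self, elabel=None) -> tuple:
        items = []
        for eid, e in self.edges.items():
            items.append((e.color, _vk(e.u), _vk(e.v)) if _vk(e.u) <= _vk(e.v) else (e.color, _vk(e.v), _vk(e.u)))
            if elabel is not None:
                items[-1] = items[-1] + (elabel(eid),)
        return tuple(sorted(map(str, items)))

    def __repr__(self) -> str:
        parts = [f"{eid}:{e.color[0]}({e.u},{e.v})" for eid, e in sorted(self.edges.items())]
        return f"ColoredGraph[{', '.join(parts)}]"


@dataclass
class Labeling:
    """Vertex and edge label maps; unmapped items fall back to defaults."""

    vertex: dict = field(default_factory=dict)
    edge: dict = field(default_factory=dict)
    default_vertex: object = "a"
    default_edge: object = TAU

    def vl(self, v):
        return self.vertex.get(v, self.default_vertex)

    def el(self, eid: int):
        return self.edge.get(eid, self.default_edge)

    def copy(self) -> "Labeling":
        return Labeling(dict(self.vertex), dict(self.edge), self.default_vertex, self.default_edge)


@dataclass
class LabeledGraph:
    graph: ColoredGraph
    labeling: Labeling = field(default_factory=Labeling)

    def vl(self, v):
        return self.labeling.vl(v)

    def el(self, eid: int):
        return self.labeling.el(eid)

    def copy(self) -> "LabeledGraph":
        return LabeledGraph(self.graph.copy(), self.labeling.copy())

    def sub(self, edge_ids) -> "LabeledGraph":
        return LabeledGraph(self.graph.subgraph(edge_ids), self.labeling)

    def canonical_form(self) -> tuple:
        return self.graph.canonical_form(elabel=self.el)


# ---------------------------------------------------------------------------
# Breakpoint graphs
# ---------------------------------------------------------------------------

@dataclass
class BreakpointGraph:
    graph: ColoredGraph
    n: int
    genome_a: Genome | None = None
    genome_b: Genome | None = None


def breakpoint_graph_from_adjacencies(
    adj_a: Counter,
    adj_b: Counter,
    n: int,
    loops: str = "def2",
) -> ColoredGraph:
    """Black edges from the A-side adjacencies, gray from the B side.

    An internal adjacency {a,b} becomes an edge {a,b}; an external {a}
    becomes {a, o}.  With ``loops='def2'`` enough monochromatic loops
    {o,o} are added so that both color degrees at o equal 2n; with
    ``loops='minimal'`` only the loops needed to balance the two color
    degrees at o are added (the two choices change e and c by the same
    amount, leaving e - c fixed).
    """
    g = ColoredGraph()
    tel = {BLACK: 0, GRAY: 0}
    for color, adjs in ((BLACK, adj_a), (GRAY, adj_b)):
        for adj in sorted(adjs):
            for _ in range(adjs[adj]):
                if adj.is_internal:
                    g.add_edge(color, adj.ext[0], adj.ext[1])
                else:
                    g.add_edge(color, adj.ext[0], TELOMERE)
                    tel[color] += 1
    if loops == "def2":
        n_loops = {c: (2 * n - tel[c]) // 2 for c in (BLACK, GRAY)}
        for c in (BLACK, GRAY):
            if 2 * n - tel[c] < 0 or (2 * n - tel[c]) % 2:
                raise ValueError("telomere count incompatible with gene count")
    elif loops == "minimal":
        diff = tel[BLACK] - tel[GRAY]
        if diff % 2:
            raise ValueError("odd telomere-count difference")
        n_loops = {BLACK: max(0, -diff) // 2, GRAY: max(0, diff) // 2}
    else:
        raise ValueError("loops must be 'def2' or 'minimal'")
    for c in (BLACK, GRAY):
        for _ in range(n_loops[c]):
            g.add_edge(c, TELOMERE, TELOMERE)
    return g


def build_breakpoint_graph(a: Genome, b: Genome, loops: str = "def2", complete: bool = False) -> BreakpointGraph:
    """Breakpoint graph G(A, B) of two genomes.

    The genomes must share their gene multiset; pass ``complete=True`` to
    equalize unequal gene content with ghost adjacencies first.
    """
    if complete:
        adj_a, adj_b = complete_gene_content(a, b)
        n = sum((a.gene_multiset | b.gene_multiset).values())
    else:
        if a.gene_multiset != b.gene_multiset:
            raise ValueError(
                "genomes have different gene content; use complete=True to add ghost adjacencies"
            )
        adj_a, adj_b = adjacencies_of(a), adjacencies_of(b)
        n = a.n_genes
    g = breakpoint_graph_from_adjacencies(adj_a, adj_b, n, loops=loops)
    return BreakpointGraph(g, n, a, b)


def is_terminal(g: ColoredGraph) -> bool:
    """True iff black and gray edge multisets (by endpoints) coincide."""
    black = Counter(e.pair() for e in g.edges.values() if e.color == BLACK)
    gray = Counter(e.pair() for e in g.edges.values() if e.color == GRAY)
    return black == gray


def is_breakpoint_shaped(g: ColoredGraph) -> bool:
    """Every vertex other than o has black degree = gray degree = 1."""
    deg: dict = defaultdict(lambda: [0, 0])
    for e in g.edges.values():
        for v in (e.u, e.v):
            deg[v][0 if e.color == BLACK else 1] += 1
    return all(d == [1, 1] for v, d in deg.items() if v != TELOMERE)


@dataclass
class PathDecomposition:
    """Structural decomposition of a breakpoint-shaped graph.

    ``circles`` contains the alternating cycles visiting no vertex twice,
    including the paths between two visits of o whose end edges have
    different colors (those close through o into circles).  AA paths end
    with two black edges at o, BB paths with two gray ones.  Loops at o
    act as zero-length pseudo-paths: a gray loop can close an AA path, a
    black loop a BB path, and a black/gray loop pair is a cycle on its
    own, which is how unequal telomere counts stay matchable.
    """

    circles: list[list[int]]
    aa_paths: list[list[int]]
    bb_paths: list[list[int]]
    black_loops: list[int]
    gray_loops: list[int]

    @property
    def p(self) -> int:
        return len(self.aa_paths)

    @property
    def total_path_edges(self) -> int:
        return sum(len(x) for x in self.aa_paths) + sum(len(x) for x in self.bb_paths)

    @property
    def left(self) -> list[tuple[str, int]]:
        """AA side of the matching: ('path', index) and ('loop', edge id)."""
        return [("path", i) for i in range(len(self.aa_paths))] + [("loop", e) for e in self.black_loops]

    @property
    def right(self) -> list[tuple[str, int]]:
        return [("path", i) for i in range(len(self.bb_paths))] + [("loop", e) for e in self.gray_loops]

    @property
    def c(self) -> int:
        """Size of a MAECD: every maximum decomposition has this many cycles."""
        if len(self.left) != len(self.right):
            raise ValueError("unbalanced matchable sets; graph is not Eulerian at o")
        return len(self.circles) + len(self.left)


def decompose_breakpoint_graph(g: ColoredGraph | BreakpointGraph) -> PathDecomposition:
    if isinstance(g, BreakpointGraph):
        g = g.graph
    if not is_breakpoint_shaped(g):
        raise ValueError("graph is not breakpoint-shaped (a non-o vertex has degree above 1/1)")

    next_edge: dict[tuple, int] = {}
    for eid in sorted(g.edges):
        e = g.edges[eid]
        for v in {e.u, e.v}:
            if v != TELOMERE:
                next_edge[(v, e.color)] = eid

    used: set[int] = set()
    black_loops = sorted(eid for eid, e in g.edges.items() if e.color == BLACK and e.is_loop)
    gray_loops = sorted(eid for eid, e in g.edges.items() if e.color == GRAY and e.is_loop)
    used.update(black_loops)
    used.update(gray_loops)

    def follow(eid: int, v) -> tuple[list[int], object, str]:
        """Walk from edge eid entered at far endpoint v until o or closure."""
        walk = [eid]
        used.add(eid)
        color = g.edges[eid].color
        while v != TELOMERE:
            nxt = next_edge[(v, GRAY if color == BLACK else BLACK)]
            if nxt in used:  # closed a circle
                return walk, v, "closed"
            walk.append(nxt)
            used.add(nxt)
            color = g.edges[nxt].color
            e = g.edges[nxt]
            v = e.v if e.u == v else e.u
        return walk, v, "telomere"

    circles: list[list[int]] = []
    aa: list[list[int]] = []
    bb: list[list[int]] = []

    # Walks out of o first.
    for eid in sorted(g.edges):
        e = g.edges[eid]
        if eid in used or e.is_loop or TELOMERE not in (e.u, e.v):
            continue
        far = e.v if e.u == TELOMERE else e.u
        walk, _, kind = follow(eid, far)
        assert kind == "telomere"
        c0, c1 = g.edges[walk[0]].color, g.edges[walk[-1]].color
        if c0 != c1:
            circles.append(walk)
        elif c0 == BLACK:
            aa.append(walk)
        else:
            bb.append(walk)

    # Remaining edges lie on circles avoiding o.
    for eid in sorted(g.edges):
        if eid in used:
            continue
        e = g.edges[eid]
        walk, _, kind = follow(eid, e.v)
        assert kind == "closed"
        circles.append(walk)

    return PathDecomposition(circles, aa, bb, black_loops, gray_loops)


# ---------------------------------------------------------------------------
# Alternating circuits, trails and the MAECD oracle
# ---------------------------------------------------------------------------

def alternating_circuit(g: ColoredGraph, edge_ids=None) -> list[tuple[int, int]]:
    """An alternating Eulerian circuit of a connected balanced edge set.

    Returns the traversal as ``[(edge_id, entry_side), ...]`` where
    ``entry_side`` marks the endpoint the walk enters the edge from; the
    walk starts with a black edge.  Backtracking search; the graphs this
    package traverses have tiny color degrees, so branching is negligible.
    """
    ids = sorted(edge_ids if edge_ids is not None else g.edges)
    if not ids:
        return []
    start = min((e for e in ids if g.edges[e].color == BLACK), default=None)
    if start is None:
        raise ValueError("edge set has no black edge")

    incident: dict = defaultdict(list)
    for eid in ids:
        e = g.edges[eid]
        incident[e.u].append((eid, 0))
        if e.v != e.u:
            incident[e.v].append((eid, 1))
        else:
            incident[e.u].append((eid, 1))

    total = len(ids)
    first = g.edges[start]
    path: list[tuple[int, int]] = []
    used: set[int] = set()

    def other(color: str) -> str:
        return GRAY if color == BLACK else BLACK

    def dfs(v, need: str) -> bool:
        if len(path) == total:
            return v == first.u and need == BLACK
        for eid, side in incident[v]:
            e = g.edges[eid]
            if eid in used or e.color != need:
                continue
            used.add(eid)
            path.append((eid, side))
            w = e.endpoint(1 - side)
            if dfs(w, other(need)):
                return True
            used.remove(eid)
            path.pop()
        return False

    used.add(start)
    path.append((start, 0))
    if dfs(first.v, GRAY):
        return path
    raise ValueError("edge set admits no alternating Eulerian circuit (not balanced/connected?)")


def closed_alternating_trails(g: ColoredGraph, through: int, edge_ids=None, proper_only: bool = False):
    """All closed alternating trails through a given edge (as edge-id frozensets).

    A closed alternating trail is exactly the edge set of one alternating
    cycle.  With ``proper_only`` the full edge set is excluded, which turns
    this into the simplicity test: c(G) = 1 iff no proper trail exists.
    """
    ids = set(edge_ids if edge_ids is not None else g.edges)
    total = len(ids)
    e0 = g.edges[through]
    results: set[frozenset] = set()

    incident: dict = defaultdict(list)
    for eid in sorted(ids):
        e = g.edges[eid]
        incident[e.u].append((eid, 0))
        if e.v != e.u:
            incident[e.v].append((eid, 1))
        else:
            incident[e.u].append((eid, 1))

    used = {through}

    def dfs(v, need: str) -> None:
        if v == e0.u and need == e0.color:
            if not (proper_only and len(used) == total):
                results.add(frozenset(used))
            # a longer trail may still close again; keep exploring
        for eid, side in incident[v]:
            e = g.edges[eid]
            if eid in used or e.color != need:
                continue
            used.add(eid)
            dfs(e.endpoint(1 - side), GRAY if need == BLACK else BLACK)
            used.remove(eid)

    dfs(e0.v, GRAY if e0.color == BLACK else BLACK)
    return results


def is_simple_cycle(g: ColoredGraph, edge_ids=None) -> bool:
    """c(G) = 1: balanced, connected, and no proper alternating sub-cycle."""
    ids = sorted(edge_ids if edge_ids is not None else g.edges)
    if not ids:
        return False
    bal: dict = defaultdict(int)
    for eid in ids:
        e = g.edges[eid]
        sgn = 1 if e.color == BLACK else -1
        bal[e.u] += sgn
        bal[e.v] += sgn
    if any(bal.values()):
        return False
    pivot = ids[0]
    trails = closed_alternating_trails(g, pivot, ids, proper_only=False)
    full = frozenset(ids)
    if full not in trails:
        return False  # not connected (or not coverable by one trail)
    return all(t == full for t in trails)


def maecd_exhaustive(g: ColoredGraph, limit: int = 8) -> list[frozenset]:
    """A maximum alternating edge-disjoint cycle decomposition, exhaustively.

    Exponential-time oracle (the problem is NP-hard in general); refuses
    graphs with more than ``limit`` black edges.
    """
    if g.e() > limit:
        raise ValueError(f"too many black edges for the exhaustive oracle (> {limit})")
    if not g.is_eulerian():
        raise ValueError("graph is not Eulerian")

    memo: dict[frozenset, list[frozenset]] = {}

    def best(remaining: frozenset) -> list[frozenset]:
        if not remaining:
            return []
        if remaining in memo:
            return memo[remaining]
        pivot = min(remaining)
        best_parts: list[frozenset] | None = None
        for trail in sorted(closed_alternating_trails(g, pivot, remaining), key=sorted):
            rest = best(remaining - trail)
            if best_parts is None or 1 + len(rest) > len(best_parts):
                best_parts = [trail] + rest
        if best_parts is None:
            raise ValueError("edges cannot be covered by alternating cycles")
        memo[remaining] = best_parts
        return best_parts

    return best(frozenset(g.edges))


def c_exhaustive(g: ColoredGraph, limit: int = 8) -> int:
    return len(maecd_exhaustive(g, limit))


def enumerate_simple_cycles(g: ColoredGraph, limit: int = 8) -> list[frozenset]:
    """All simple cycles (edge subsets with c = 1) of a small graph."""
    if g.e() > limit:
        raise ValueError(f"too many black edges for exhaustive cycle listing (> {limit})")
    seen: set[frozenset] = set()
    for pivot in sorted(g.edges):
        for trail in closed_alternating_trails(g, pivot):
            if trail not in seen and is_simple_cycle(g, trail):
                seen.add(trail)
    return sorted(seen, key=sorted)


# ---------------------------------------------------------------------------
# Vertex splitting: simple cycle -> circles
# ---------------------------------------------------------------------------

def _deg2_vertices(g: ColoredGraph) -> list:
    deg: dict = defaultdict(lambda: [0, 0])
    for e in g.edges.values():
        for v in (e.u, e.v):
            deg[v][0 if e.color == BLACK else 1] += 1
    return sorted((v for v, d in deg.items() if d == [2, 2]), key=_vk)


def split_degree_two_vertex(s: LabeledGraph, v) -> list[LabeledGraph]:
    """Split a degree-2/2 vertex of a simple cycle into v1, v2.

    Returns one labeled graph when v carries a monochromatic loop (the
    loop becomes the edge {v1, v2}), otherwise the two graphs given by
    the two alternation-preserving dart pairings.  Every returned graph
    is again a simple cycle; vertex and edge labels are preserved.
    """
    g = s.graph
    if g.degree(v, BLACK) != 2 or g.degree(v, GRAY) != 2:
        raise ValueError(f"vertex {v} does not have black and gray degree 2")
    if not is_simple_cycle(g):
        raise ValueError("graph is not a simple cycle")

    v1 = ("split", _vk(v), 1)
    v2 = ("split", _vk(v), 2)

    def rebuilt(assign: dict[tuple[int, int], object]) -> LabeledGraph:
        g2 = ColoredGraph()
        g2._next_id = g._next_id
        for eid in sorted(g.edges):
            e = g.edges[eid]
            u = assign.get((eid, 0), e.u)
            w = assign.get((eid, 1), e.v)
            g2.edges[eid] = Edge(e.color, u, w)
        lab = s.labeling.copy()
        lab.vertex[v1] = s.vl(v)
        lab.vertex[v2] = s.vl(v)
        return LabeledGraph(g2, lab)

    loops = [eid for eid in sorted(g.edges) if g.edges[eid].is_loop and g.edges[eid].u == v]
    darts = {c: [(eid, side) for eid, side in g.incident(v, c) if not g.edges[eid].is_loop] for c in (BLACK, GRAY)}

    if len(loops) == 2:  # one loop per color: splitting yields a 2-vertex circle
        a, b = loops
        return [rebuilt({(a, 0): v1, (a, 1): v2, (b, 0): v1, (b, 1): v2})]
    if len(loops) == 1:
        (lp,) = loops
        other = darts[GRAY] if g.edges[lp].color == BLACK else darts[BLACK]
        d1, d2 = other
        return [rebuilt({(lp, 0): v1, (lp, 1): v2, d1: v1, d2: v2})]
    b1, b2 = darts[BLACK]
    g1, g2d = darts[GRAY]
    return [
        rebuilt({b1: v1, g1: v1, b2: v2, g2d: v2}),
        rebuilt({b1: v1, g2d: v1, b2: v2, g1: v2}),
    ]


def circ(s: LabeledGraph) -> list[LabeledGraph]:
    """The set of labeled circles obtained by splitting all degree-2 vertices.

    The result has at most 2^deg2(S) members; a minimum-cost parsimonious
    scenario for the simple cycle S equals the minimum over these circles.
    """
    current = [s]
    while True:
        d2 = _deg2_vertices(current[0].graph)
        if not d2:
            return current
        v = d2[0]
        nxt: list[LabeledGraph] = []
        for member in current:
            nxt.extend(split_degree_two_vertex(member, v))
        current = nxt


# ---------------------------------------------------------------------------
# Raw colored-graph I/O: TSV edge list (edge_id, color, u, v, label)
# ---------------------------------------------------------------------------

def _parse_vertex(tok: str):
    if tok == TELOMERE:
        return TELOMERE
    try:
        return Extremity.parse(tok)
    except ValueError:
        return tok


def read_edge_list(path) -> LabeledGraph:
    g = ColoredGraph()
    lab = Labeling()
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"edge line needs at least 4 TSV fields: {raw!r}")
            eid, color, u, v = parts[:4]
            g.add_edge(color, _parse_vertex(u), _parse_vertex(v), eid=int(eid))
            if len(parts) > 4 and parts[4]:
                lab.edge[int(eid)] = parts[4]
    return LabeledGraph(g, lab)


def write_edge_list(path, gl: LabeledGraph) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for eid in sorted(gl.graph.edges):
            e = gl.graph.edges[eid]
            fh.write(f"{eid}\t{e.color}\t{e.u}\t{e.v}\t{gl.el(eid)}\n")
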