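"""Seeded generators and worked-example fixtures.

Everything here is a pure function of its configuration and seed, so the
whole test surface (random genomes, scrambles with a known upper bound
on the distance, random symmetric cost tables, labeled breakpoint
graphs) is reproducible without external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomes import (
    Adjacency,
    Chromosome,
    DcjOperation,
    Genome,
    adjacencies_of,
    apply_dcj,
)
from .colored_graphs import (
    BLACK,
    GRAY,
    BreakpointGraph,
    ColoredGraph,
    LabeledGraph,
    Labeling,
    build_breakpoint_graph,
)
from .cost_models import PhiFModel, PhiMatrix, model_phi_f
from .scenarios import TwoBreak

__all__ = [
    "GeneratorConfig",
    "random_genome",
    "scramble",
    "random_phi",
    "random_instance",
    "fixtures",
    "all_genomes",
    "simple_cycles_with_two_degree2_vertices",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Conditions for one synthetic instance.

    Defaults give the small, fully checkable regime the solvers are
    exercised on: a handful of genes on one chromosome, a few scramble
    moves, and a small color alphabet with uniform costs.
    """

    n: int = 3
    chromosomes: int = 1
    circular: bool = False
    k: int = 3
    labels: tuple = ("x", "y", "z")
    phi_low: float = 0.0
    phi_high: float = 1.0
    seed: int = 0


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_genome(n: int, chromosomes: int = 1, circular=False, seed=0, name: str = "") -> Genome:
    """A uniformly random signed order split into the requested chromosomes."""
    rng = _rng(seed)
    if n == 0:
        return Genome((), name)
    if not 1 <= chromosomes <= n:
        raise ValueError("need 1 <= chromosomes <= n")
    perm = rng.permutation(np.arange(1, n + 1))
    signs = rng.choice([-1, 1], size=n)
    genes = [int(p * s) for p, s in zip(perm, signs)]
    cuts = sorted(rng.choice(np.arange(1, n), size=chromosomes - 1, replace=False)) if chromosomes > 1 else []
    bounds = [0, *cuts, n]
    flags = list(circular) if not isinstance(circular, bool) else [circular] * chromosomes
    chroms = tuple(
        Chromosome(tuple(genes[a:b]), bool(f)) for a, b, f in zip(bounds, bounds[1:], flags)
    )
    return Genome(chroms, name)


def _random_dcj(genome: Genome, rng, weights=None) -> DcjOperation | None:
    adjs = sorted(adjacencies_of(genome).elements())
    internals = [a for a in adjs if a.is_internal]
    externals = [a for a in adjs if a.is_external]
    forms = []
    if len(internals) >= 2:
        forms.append("ii")
    if internals and externals:
        forms.append("ie")
    if internals:
        forms.append("fission")
    if len(externals) >= 2:
        forms.append("fusion")
    if not forms:
        return None
    w = np.array([(weights or {}).get(f, 1.0) for f in forms], dtype=float)
    form = forms[int(rng.choice(len(forms), p=w / w.sum()))]
    if form == "ii":
        i, j = rng.choice(len(internals), size=2, replace=False)
        (a, b), (c, d) = internals[i].ext, internals[j].ext
        if rng.integers(2):
            prod = (Adjacency.internal(a, c), Adjacency.internal(b, d))
        else:
            prod = (Adjacency.internal(a, d), Adjacency.internal(b, c))
        return DcjOperation((internals[i], internals[j]), prod)
    if form == "ie":
        i = int(rng.integers(len(internals)))
        j = int(rng.integers(len(externals)))
        (a, b), (c,) = internals[i].ext, externals[j].ext
        if rng.integers(2):
            prod = (Adjacency.internal(a, c), Adjacency.external(b))
        else:
            prod = (Adjacency.internal(b, c), Adjacency.external(a))
        return DcjOperation((internals[i], externals[j]), prod)
    if form == "fission":
        i = int(rng.integers(len(internals)))
        a, b = internals[i].ext
        return DcjOperation((internals[i],), (Adjacency.external(a), Adjacency.external(b)))
    i, j = rng.choice(len(externals), size=2, replace=False)
    (a,), (b,) = externals[i].ext, externals[j].ext
    return DcjOperation((externals[i], externals[j]), (Adjacency.internal(a, b),))


def scramble(genome: Genome, k: int, seed=0, weights: dict | None = None) -> tuple[Genome, list[DcjOperation]]:
    """Apply k random valid DCJs; the result is at distance at most k.

    ``weights`` reweights the four rewrite forms (keys 'ii', 'ie',
    'fission', 'fusion'); the default is uniform over the applicable
    forms.  Returns the scrambled genome and the applied operations.
    """
    rng = _rng(seed)
    ops: list[DcjOperation] = []
    current = genome
    for _ in range(k):
        op = _random_dcj(current, rng, weights)
        if op is None:
            break
        current = apply_dcj(current, op)
        ops.append(op)
    return current, ops


def random_phi(labels, seed=0, low: float = 0.0, high: float = 1.0, integer: bool = False) -> PhiMatrix:
    rng = _rng(seed)
    k = len(labels)
    if integer:
        arr = rng.integers(int(low), int(high) + 1, size=(k, k)).astype(float)
    else:
        arr = rng.uniform(low, high, size=(k, k))
    arr = np.triu(arr) + np.triu(arr, 1).T
    return PhiMatrix.from_array(labels, arr)


def random_instance(cfg: GeneratorConfig) -> tuple[LabeledGraph, PhiFModel, BreakpointGraph]:
    """A random labeled breakpoint graph with a random fixed-label model.

    Genome A is random, B is A scrambled by k DCJs; every black edge
    (o-loops included, so fissions and fusions stay members of the
    operation set) gets a uniform label from the alphabet; gray edges
    keep the terminal label.
    """
    rng = _rng(cfg.seed)
    a = random_genome(cfg.n, cfg.chromosomes, cfg.circular, rng, name="A")
    b, _ = scramble(a, cfg.k, rng)
    b = Genome(b.chromosomes, "B")
    bg = build_breakpoint_graph(a, b)
    lab = Labeling()
    for eid in bg.graph.black_ids():
        lab.edge[eid] = cfg.labels[int(rng.integers(len(cfg.labels)))]
    gl = LabeledGraph(bg.graph, lab)
    phi = random_phi(cfg.labels, rng, cfg.phi_low, cfg.phi_high)
    return gl, model_phi_f(phi), bg


# ---------------------------------------------------------------------------
# Exhaustive small-universe enumerations
# ---------------------------------------------------------------------------

def simple_cycles_with_two_degree2_vertices(max_black: int = 8) -> list[LabeledGraph]:
    """All simple alternating cycles with exactly two degree-2/2 vertices.

    A simple cycle is a single closed alternating walk, so every such
    graph arises from a cyclic vertex sequence v_0 .. v_{2m-1} (edge k
    joins v_k to v_{k+1}, black at even k) in which exactly two values
    repeat, each exactly twice.  Candidates are enumerated over all
    disjoint position pairs, deduplicated up to rotation (by two, to
    keep the color phase), reflection and relabeling, and kept when no
    proper alternating sub-cycle exists.
    """
    import itertools as it

    from .colored_graphs import is_simple_cycle

    found: dict[tuple, LabeledGraph] = {}
    for m in range(2, max_black + 1):
        p = 2 * m
        pairs = list(it.combinations(range(p), 2))
        for (i1, j1), (i2, j2) in it.combinations(pairs, 2):
            if len({i1, j1, i2, j2}) < 4:
                continue
            vid = list(range(p))
            vid[j1] = i1
            vid[j2] = i2
            canon = _walk_canon(vid)
            if canon in found:
                continue
            g = ColoredGraph()
            for k in range(p):
                g.add_edge(BLACK if k % 2 == 0 else GRAY, vid[k], vid[(k + 1) % p])
            deg2 = {
                v
                for v in g.vertices()
                if g.degree(v, BLACK) == 2 and g.degree(v, GRAY) == 2
            }
            if deg2 != {i1, i2}:
                continue
            if is_simple_cycle(g):
                found[canon] = LabeledGraph(g)
    return list(found.values())


def _walk_canon(vid: list[int]) -> tuple:
    """Canonical form of a cyclic alternating walk under rotation by two,
    reflection (with phase restored), and vertex relabeling."""
    p = len(vid)
    best = None
    for seq in (vid, vid[::-1]):
        for shift in range(0, p, 2):
            rot = seq[shift:] + seq[:shift]
            relabel: dict[int, int] = {}
            key = tuple(relabel.setdefault(v, len(relabel)) for v in rot)
            if best is None or key < best:
                best = key
    return best


def all_genomes(genes: tuple[int, ...]) -> list[Genome]:
    """Every genome over the given genes (each exactly once), mixing
    linear and circular chromosomes, up to chromosome order, traversal
    direction and circular rotation."""
    import itertools as it

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for k in range(len(rest) + 1):
            for others in it.combinations(rest, k):
                block = (first, *others)
                remaining = tuple(x for x in rest if x not in others)
                for more in partitions(remaining):
                    yield [block] + more

    out: dict[tuple, Genome] = {}
    for blocks in partitions(tuple(genes)):
        per_block = []
        for block in blocks:
            arrangements = []
            for perm in it.permutations(block):
                for signs in it.product((1, -1), repeat=len(block)):
                    for circular in (False, True):
                        arrangements.append(Chromosome(tuple(s * g for s, g in zip(signs, perm)), circular))
            per_block.append(arrangements)
        for choice in it.product(*per_block):
            g = Genome(tuple(choice)).canonical()
            key = tuple((c.genes, c.circular) for c in g.chromosomes)
            out.setdefault(key, g)
    return list(out.values())


# ---------------------------------------------------------------------------
# Worked-example fixtures
# ---------------------------------------------------------------------------

def fixtures() -> dict:
    """Small named instances used across the test suite.

    ``two_cycle_graph`` is the minimal graph whose length-1 scenario has
    a 2-component trajectory graph: the alternating 4-cycle sorted by
    the single 2-break, plus a second, already-terminal simple cycle on
    fresh vertices.
    """
    fx: dict = {}

    fx["reversal_pair"] = (
        Genome.from_orders([1, 2, -3], name="A"),
        Genome.from_orders([1, -2, -3], name="B"),
    )

    # 4-cycle on a, b, c, d plus one terminal black/gray pair on e, f.
    g3 = ColoredGraph()
    e_ab = g3.add_edge(BLACK, "a", "b")
    e_dc = g3.add_edge(BLACK, "d", "c")
    e_ef = g3.add_edge(BLACK, "e", "f")
    g3.add_edge(GRAY, "a", "d")
    g3.add_edge(GRAY, "b", "c")
    g3.add_edge(GRAY, "e", "f")
    fx["two_cycle_graph"] = g3
    fx["two_cycle_scenario"] = [TwoBreak(e_ab, e_dc, 0, 0)]  # {a,b},{d,c} -> {a,d},{b,c}

    # Simple cycle whose degree-2 vertex carries a gray loop.
    up = ColoredGraph()
    up.add_edge(BLACK, "v", "a")
    up.add_edge(BLACK, "b", "v")
    up.add_edge(GRAY, "a", "b")
    up.add_edge(GRAY, "v", "v")
    fx["loop_split_cycle"] = LabeledGraph(up)

    # 6-edge simple cycle with a loop-free degree-2 vertex.
    low = ColoredGraph()
    low.add_edge(BLACK, "v", "x")
    low.add_edge(BLACK, "y", "v")
    low.add_edge(BLACK, "z", "t")
    low.add_edge(GRAY, "x", "y")
    low.add_edge(GRAY, "v", "z")
    low.add_edge(GRAY, "t", "v")
    fx["plain_split_cycle"] = LabeledGraph(low)

    # Duplicated gene 1; gene 4 only in A, one copy of gene 2 missing in A.
    fx["duplicated_gene_pair"] = (
        Genome.from_orders([1, -2, -3], [4, 1], circular=[True, False], name="A"),
        Genome.from_orders([1, -2], [1, 2, 3], circular=[True, True], name="B"),
    )
    return fx
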