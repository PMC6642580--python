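"""Colored multigraphs: breakpoint graphs, decompositions, splitting."""

from collections import Counter

import pytest

from mcps.colored_graphs import (
    BLACK,
    GRAY,
    TELOMERE,
    ColoredGraph,
    LabeledGraph,
    Labeling,
    build_breakpoint_graph,
    circ,
    decompose_breakpoint_graph,
    enumerate_simple_cycles,
    is_simple_cycle,
    is_terminal,
    maecd_exhaustive,
    read_edge_list,
    split_degree_two_vertex,
    write_edge_list,
)
from mcps.genomes import Extremity, Genome
from mcps.synthetic import GeneratorConfig, random_genome, random_instance, scramble


def ext(s):
    return Extremity.parse(s)


def test_build_breakpoint_graph_worked_example(fx):
    a, b = fx["reversal_pair"]
    bg = build_breakpoint_graph(a, b)
    g = bg.graph
    blacks = Counter(e.pair() for e in g.edges.values() if e.color == BLACK)
    grays = Counter(e.pair() for e in g.edges.values() if e.color == GRAY)
    assert blacks == Counter(
        [
            (ext("1t"), TELOMERE),
            (ext("1h"), ext("2t")),
            (ext("2h"), ext("3h")),
            (ext("3t"), TELOMERE),
            (TELOMERE, TELOMERE),
            (TELOMERE, TELOMERE),
        ]
    )
    assert grays == Counter(
        [
            (ext("1t"), TELOMERE),
            (ext("1h"), ext("2h")),
            (ext("2t"), ext("3h")),
            (ext("3t"), TELOMERE),
            (TELOMERE, TELOMERE),
            (TELOMERE, TELOMERE),
        ]
    )
    assert g.degree(TELOMERE, BLACK) == g.degree(TELOMERE, GRAY) == 2 * bg.n
    assert g.is_eulerian()


def test_terminal_graphs(fx):
    a, b = fx["reversal_pair"]
    assert is_terminal(build_breakpoint_graph(b, b).graph)
    assert not is_terminal(build_breakpoint_graph(a, b).graph)
    g = ColoredGraph()
    g.add_edge(BLACK, "a", "b")
    g.add_edge(GRAY, "a", "c")
    assert not is_terminal(g)
    assert is_terminal(ColoredGraph())


def test_circular_genomes_loops_only():
    a = Genome.from_orders([1, 2, 3], circular=True)
    b = Genome.from_orders([1, -3, 2], circular=True)
    g = build_breakpoint_graph(a, b).graph
    loops = [e for e in g.edges.values() if e.is_loop]
    assert len(loops) == 2 * 3  # n per color
    assert all(e.u == TELOMERE for e in loops)


def test_decompose_worked_example(fx):
    a, b = fx["reversal_pair"]
    bg = build_breakpoint_graph(a, b)
    dec = decompose_breakpoint_graph(bg.graph)
    assert len(dec.circles) == 3  # two closed through o, one avoiding o
    assert len(dec.black_loops) == len(dec.gray_loops) == 2
    assert dec.p == 0 and not dec.bb_paths
    assert dec.c == 5
    assert bg.graph.e() == 6
    # the exhaustive oracle agrees on every MAECD's size
    assert len(maecd_exhaustive(bg.graph)) == 5


def test_decompose_terminal_is_trivial(fx):
    _, b = fx["reversal_pair"]
    g = build_breakpoint_graph(b, b).graph
    dec = decompose_breakpoint_graph(g)
    assert dec.c == g.e()


def test_unequal_telomere_counts():
    a = Genome.from_orders([1, 2])
    b = Genome.from_orders([1], [2])
    g = build_breakpoint_graph(a, b).graph
    dec = decompose_breakpoint_graph(g)
    # the surplus gray-ended path is closed by a black o-loop pseudo-path
    assert len(dec.aa_paths) + len(dec.black_loops) == len(dec.bb_paths) + len(dec.gray_loops)
    assert dec.c == len(maecd_exhaustive(g))


def test_maecd_examples():
    g = ColoredGraph()
    g.add_edge(BLACK, "a", "b")
    g.add_edge(BLACK, "c", "d")
    g.add_edge(GRAY, "a", "d")
    g.add_edge(GRAY, "b", "c")
    assert len(maecd_exhaustive(g)) == 1
    assert is_simple_cycle(g)

    t = ColoredGraph()
    for i in range(3):
        t.add_edge(BLACK, 2 * i, 2 * i + 1)
        t.add_edge(GRAY, 2 * i, 2 * i + 1)
    assert len(maecd_exhaustive(t)) == t.e() == 3

    bad = ColoredGraph()
    bad.add_edge(BLACK, "a", "b")
    with pytest.raises(ValueError):
        maecd_exhaustive(bad)


def test_loop_count_neutrality(fx):
    a, b = fx["reversal_pair"]
    g = build_breakpoint_graph(a, b).graph
    e0, c0 = g.e(), decompose_breakpoint_graph(g).c
    g2 = g.copy()
    g2.add_edge(BLACK, TELOMERE, TELOMERE)
    g2.add_edge(GRAY, TELOMERE, TELOMERE)
    assert g2.e() == e0 + 1
    assert decompose_breakpoint_graph(g2).c == c0 + 1


def test_enumerate_simple_cycles_basics(fx):
    up = fx["loop_split_cycle"].graph
    assert enumerate_simple_cycles(up) == [frozenset(up.edges)]
    two = ColoredGraph()
    for base in (0, 10):
        two.add_edge(BLACK, base, base + 1, eid=base)
        two.add_edge(GRAY, base, base + 1, eid=base + 1)
    found = enumerate_simple_cycles(two)
    assert sorted(map(sorted, found)) == [[0, 1], [10, 11]]


@pytest.mark.parametrize("seed", range(6))
def test_simple_cycle_count_on_breakpoint_graphs(seed):
    gl, _, bg = random_instance(GeneratorConfig(n=2, k=2, circular=bool(seed % 2), seed=seed))
    dec = decompose_breakpoint_graph(bg.graph)
    cycles = enumerate_simple_cycles(bg.graph, limit=8)
    # circles are forced; every other simple cycle is a union of one
    # AA-side element with one BB-side element (o-loops included)
    assert len(cycles) == len(dec.circles) + len(dec.left) * len(dec.right)
    for cyc in cycles:
        assert is_simple_cycle(bg.graph, cyc)


def test_split_counts(fx):
    assert len(split_degree_two_vertex(fx["loop_split_cycle"], "v")) == 1
    parts = split_degree_two_vertex(fx["plain_split_cycle"], "v")
    assert len(parts) == 2
    for part in parts:
        assert is_simple_cycle(part.graph)
        # labels preserved, edge ids preserved
        assert sorted(part.graph.edges) == sorted(fx["plain_split_cycle"].graph.edges)
    with pytest.raises(ValueError):
        split_degree_two_vertex(fx["loop_split_cycle"], "a")


def test_split_merge_inverse(fx):
    s = fx["plain_split_cycle"]
    for part in split_degree_two_vertex(s, "v"):
        merged = Counter()
        for eid, e in part.graph.edges.items():
            u = "v" if isinstance(e.u, tuple) else e.u
            w = "v" if isinstance(e.v, tuple) else e.v
            merged[(e.color, tuple(sorted((str(u), str(w)))))] += 1
        original = Counter(
            (e.color, tuple(sorted((str(e.u), str(e.v))))) for e in s.graph.edges.values()
        )
        assert merged == original


def test_split_loop_pair():
    g = ColoredGraph()
    g.add_edge(BLACK, TELOMERE, TELOMERE)
    g.add_edge(GRAY, TELOMERE, TELOMERE)
    out = split_degree_two_vertex(LabeledGraph(g), TELOMERE)
    assert len(out) == 1
    (circle,) = out
    assert not any(e.is_loop for e in circle.graph.edges.values())


def test_circ_sizes(fx):
    assert len(circ(fx["loop_split_cycle"])) == 1
    lower = circ(fx["plain_split_cycle"])
    assert len(lower) == 2
    for member in lower:
        assert all(
            member.graph.degree(v, BLACK) == member.graph.degree(v, GRAY) == 1
            for v in member.graph.vertices()
        )


def test_edge_list_round_trip(tmp_path, fx):
    gl = fx["plain_split_cycle"].copy()
    gl.labeling.edge = {eid: f"l{eid}" for eid in gl.graph.edges}
    path = tmp_path / "graph.tsv"
    write_edge_list(path, gl)
    back = read_edge_list(path)
    assert back.graph.canonical_form(back.el) == gl.graph.canonical_form(gl.el)
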