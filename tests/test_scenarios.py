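"""2-break scenarios, distance, trajectory graphs, DCJ translation."""

import pytest

from mcps.colored_graphs import (
    BLACK,
    GRAY,
    ColoredGraph,
    build_breakpoint_graph,
    is_simple_cycle,
    is_terminal,
)
from mcps.genomes import Genome
from mcps.scenarios import (
    TwoBreak,
    apply_scenario,
    apply_two_break,
    d2b,
    decompose_scenario,
    parsimonious_scenario,
    trajectory,
    two_break_scenario_to_dcj,
)
from mcps.synthetic import random_genome, scramble


def test_apply_two_break_reaches_terminal(fx):
    g = fx["two_cycle_graph"]
    (tb,) = fx["two_cycle_scenario"]
    g2, (f1, f2) = apply_two_break(g, tb)
    assert is_terminal(g2)
    # gray edges untouched
    assert [e for e in g2.edges.values() if e.color == GRAY] == [
        e for e in g.edges.values() if e.color == GRAY
    ]


def test_two_break_inverse():
    g = ColoredGraph()
    a = g.add_edge(BLACK, 1, 2)
    b = g.add_edge(BLACK, 3, 4)
    g.add_edge(GRAY, 1, 3)
    g.add_edge(GRAY, 2, 4)
    g2, (f1, f2) = apply_two_break(g, TwoBreak(a, b, 0, 0))
    g3, _ = apply_two_break(g2, TwoBreak(f1, f2, 0, 0))
    assert g3.canonical_form() == g.canonical_form()
    with pytest.raises(ValueError):
        apply_two_break(g, TwoBreak(a, 99, 0, 0))


def test_two_break_on_loop_is_fission():
    g = ColoredGraph()
    ab = g.add_edge(BLACK, "a", "b")
    loop = g.add_edge(BLACK, "o", "o")
    g2, (f1, f2) = apply_two_break(g, TwoBreak(ab, loop, 0, 0))
    pairs = sorted(tuple(sorted((str(g2.edges[f].u), str(g2.edges[f].v)))) for f in (f1, f2))
    assert pairs == [("a", "o"), ("b", "o")]


def test_d2b_examples(fx):
    a, b = fx["reversal_pair"]
    assert d2b(build_breakpoint_graph(a, b).graph) == 1
    assert d2b(build_breakpoint_graph(b, b).graph) == 0


@pytest.mark.parametrize("seed", range(8))
def test_d2b_bounded_by_scramble_length(seed):
    a = random_genome(4, chromosomes=1 + seed % 2, seed=seed)
    k = 3
    b, ops = scramble(a, k, seed=seed + 100)
    assert d2b(build_breakpoint_graph(a, b).graph) <= len(ops) <= k


def test_parsimonious_scenario_properties(fx):
    a, b = fx["reversal_pair"]
    g = build_breakpoint_graph(a, b).graph
    rho = parsimonious_scenario(g)
    assert len(rho) == 1
    assert is_terminal(apply_scenario(g, rho))

    gb = build_breakpoint_graph(b, b).graph
    assert parsimonious_scenario(gb) == []


@pytest.mark.parametrize("seed", range(8))
def test_parsimonious_scenario_random(seed):
    a = random_genome(4, seed=seed)
    b, _ = scramble(a, 3, seed=seed + 50)
    g = build_breakpoint_graph(a, b).graph
    rho = parsimonious_scenario(g)
    assert len(rho) == d2b(g)
    assert is_terminal(apply_scenario(g, rho))


def test_trajectory_components(fx):
    g = fx["two_cycle_graph"]
    assert trajectory(g, []).n_components == g.e()
    assert trajectory(g, fx["two_cycle_scenario"]).n_components == 2


@pytest.mark.parametrize("seed", range(6))
def test_decompose_scenario_of_parsimonious(seed):
    a = random_genome(4, chromosomes=1 + seed % 2, seed=seed)
    b, _ = scramble(a, 4, seed=seed + 77)
    g = build_breakpoint_graph(a, b).graph
    rho = parsimonious_scenario(g)
    parts = decompose_scenario(g, rho)
    from mcps.scenarios import c_of

    assert len(parts) == c_of(g)
    all_edges = set()
    for h, sub_rho in parts:
        assert is_simple_cycle(h)
        assert is_terminal(apply_scenario(h, sub_rho))
        assert not (all_edges & set(h.edges))
        all_edges |= set(h.edges)
    assert all_edges == set(g.edges)
    # concatenating the subscenarios in reversed component order still works
    replayed = list(reversed([tb for _, sub in parts for tb in sub]))
    flat = [tb for _, sub in reversed(parts) for tb in sub]
    assert is_terminal(apply_scenario(g, flat))
    assert len(flat) == len(rho)


def test_nonparsimonious_component_lower_bound(fx):
    # k >= e(G) - m for any scenario of length m: waste moves by doing,
    # undoing, and redoing the single useful 2-break.
    g = fx["two_cycle_graph"]
    (tb,) = fx["two_cycle_scenario"]
    g2, (f1, f2) = apply_two_break(g, tb)
    g3, (h1, h2) = apply_two_break(g2, TwoBreak(f1, f2, 0, 0))
    rho = [tb, TwoBreak(f1, f2, 0, 0, h1, h2), TwoBreak(h1, h2, 0, 0)]
    traj = trajectory(g, rho)
    assert traj.n_components >= g.e() - len(rho)


def test_dcj_translation_worked_example(fx):
    a, b = fx["reversal_pair"]
    bg = build_breakpoint_graph(a, b)
    rho = parsimonious_scenario(bg.graph)
    ops = two_break_scenario_to_dcj(a, b, rho, bg)
    assert len(ops) == 1
    consumed = {str(x) for x in ops[0].consumed}
    produced = {str(x) for x in ops[0].produced}
    assert consumed == {"1h-2t", "2h-3h"}
    assert produced == {"1h-2h", "2t-3h"}


@pytest.mark.parametrize("seed", range(8))
def test_dcj_round_trip_random(seed):
    a = random_genome(5, chromosomes=1 + seed % 3, seed=seed)
    b, _ = scramble(a, 4, seed=seed + 11)
    bg = build_breakpoint_graph(a, b)
    rho = parsimonious_scenario(bg.graph)
    ops = two_break_scenario_to_dcj(a, b, rho, bg)  # raises if replay misses B
    assert len(ops) == d2b(bg.graph)
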