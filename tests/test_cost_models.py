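"""Operation-set contracts, costs, scenario validation, p-sufficiency."""

import math

import pytest

from mcps.colored_graphs import GRAY, TAU, LabeledGraph, Labeling, build_breakpoint_graph
from mcps.cost_models import (
    OBreak,
    OChange,
    OScenario,
    PhiMatrix,
    ScenarioError,
    labeled_terminal,
    model_hic,
    model_phi_f,
    model_phi_l,
    model_vertex,
    replay,
    settle_groups,
    validate_and_cost,
)
from mcps.genomes import Genome
from mcps.scenarios import d2b, parsimonious_scenario
from mcps.synthetic import GeneratorConfig, random_instance


def test_phi_matrix_contracts():
    with pytest.raises(ValueError):
        PhiMatrix.from_array(("x", "y"), [[0, 1], [2, 0]])  # asymmetric
    with pytest.raises(ValueError):
        PhiMatrix.from_array(("x", "y"), [[0, -1], [-1, 0]])  # negative
    phi = PhiMatrix.indicator(("x", "y"))
    assert phi("x", "x") == 0 and phi("x", "y") == 1
    assert math.isinf(phi("x", "missing"))


def test_phi_f_membership_and_costs():
    m = model_phi_f(PhiMatrix.indicator(("x", "y")))
    # 2-breaks keep their two labels, in either product assignment
    assert m.is_break("a", "a", "a", "a", "x", "y", "x", "y")
    assert m.is_break("a", "a", "a", "a", "x", "y", "y", "x")
    assert not m.is_break("a", "a", "a", "a", "x", "y", "x", "x")
    assert not m.is_break("a", "a", "a", "a", TAU, "y", TAU, "y")
    assert m.break_cost("a", "a", "a", "a", "x", "y", "x", "y") == 1.0
    assert m.break_cost("a", "a", "a", "a", "x", "x", "x", "x") == 0.0
    # relabeling to the terminal label is the only change, and it is free
    assert m.is_change("a", "a", "x", TAU) and m.change_cost("a", "a", "x", TAU) == 0.0
    assert not m.is_change("a", "a", "x", "y")
    with pytest.raises(ValueError):
        model_phi_f(PhiMatrix.from_array(("x", TAU), [[0, 0], [0, 0]]))


def test_hic_model():
    hic = {("i1", "i1"): 3.0, ("i1", "i2"): 5.0, ("i2", "i2"): 1.0}
    m = model_hic({"e": "i1"}, hic)
    assert m.phi("i1", "i2") == 0.0  # the largest contact value costs nothing
    assert m.phi("i2", "i2") == 4.0
    with pytest.raises(ValueError):
        model_hic({"e": "unknown"}, hic)
    flat = model_hic({}, {("i1", "i1"): 2.0, ("i1", "i2"): 2.0, ("i2", "i2"): 2.0})
    assert flat.phi("i1", "i2") == flat.phi("i1", "i1") == 0.0


def test_phi_l_membership_and_costs():
    m = model_phi_l()
    assert m.is_break("a", "a", "a", "a", 5, 7, 4, 8)
    assert not m.is_break("a", "a", "a", "a", 5, 7, 4, 9)
    assert m.change_cost("a", "a", 5, 3) == 2.0
    assert {zt for zt, _ in m.break_options("a", "a", "a", "a", 1, 2)} == {
        (0, 3),
        (1, 2),
        (2, 1),
        (3, 0),
    }


def test_vertex_model_contract():
    m = model_vertex(lambda a, b, c, d: a + b + c + d)
    assert m.is_break(1, 2, 3, 4, TAU, TAU, TAU, TAU)
    assert m.break_cost(1, 2, 3, 4, TAU, TAU, TAU, TAU) == 10.0
    assert not m.is_break(1, 2, 3, 4, "x", TAU, "x", TAU)
    with pytest.raises(ValueError):
        model_vertex(lambda x, y: 0)  # not a function of the 4 vertex labels


def test_validate_empty_scenario_on_terminal():
    b = Genome.from_orders([1, -2])
    gl = LabeledGraph(build_breakpoint_graph(b, b).graph, Labeling())
    m = model_phi_f(PhiMatrix.indicator(("x",)))
    assert validate_and_cost(gl, OScenario([]), m) == (0.0, 0)
    assert labeled_terminal(gl)


def test_validate_detects_bad_final_labels():
    b = Genome.from_orders([1, -2])
    lab = Labeling()
    g = build_breakpoint_graph(b, b).graph
    lab.edge[g.black_ids()[0]] = "x"
    gl = LabeledGraph(g, lab)
    m = model_phi_f(PhiMatrix.indicator(("x",)))
    with pytest.raises(ScenarioError, match="labeled multisets differ"):
        validate_and_cost(gl, OScenario([]), m)
    # one free relabel to tau fixes it
    fix = OScenario([OChange(g.black_ids()[0], TAU)])
    assert validate_and_cost(gl, fix, m) == (0.0, 0)


def test_validate_reports_failing_step():
    b = Genome.from_orders([1, -2])
    lab = Labeling()
    g = build_breakpoint_graph(b, b).graph
    gl = LabeledGraph(g, lab)
    m = model_phi_f(PhiMatrix.indicator(("x",)))
    bad = OScenario([OChange(g.black_ids()[0], "y")])  # y is not the terminal label
    with pytest.raises(ScenarioError) as err:
        validate_and_cost(gl, bad, m)
    assert err.value.step == 0


def _lift(gl, rho, products):
    """Lift a graph-level parsimonious scenario into an O-scenario that
    distributes labels per the given product rule, then settle labels."""
    steps = []
    state = gl.copy()
    for tb in rho:
        x, y = state.el(tb.e1), state.el(tb.e2)
        z, t = products(x, y)
        step = OBreak(tb.e1, tb.e2, tb.s1, tb.s2, z, t, tb.p1, tb.p2)
        steps.append(step)
        state, _, _ = replay(state, OScenario([step]), model=None)
    return OScenario(steps), state


@pytest.mark.parametrize("seed", range(5))
def test_phi_f_is_p_sufficient(seed):
    gl, model, bg = random_instance(GeneratorConfig(n=3, k=3, seed=seed))
    rho = parsimonious_scenario(gl.graph)
    scen, state = _lift(gl, rho, lambda x, y: (x, y))
    cost, changes = model.settle(settle_groups(state))
    scen.steps.extend(OChange(e, lab) for e, lab in changes)
    c, k = validate_and_cost(gl, scen, model)
    assert k == d2b(gl.graph)


@pytest.mark.parametrize("seed", range(5))
def test_phi_l_is_p_sufficient(seed):
    gl, _, bg = random_instance(GeneratorConfig(n=3, k=3, seed=seed))
    model = model_phi_l()
    lab = Labeling(default_edge=0)
    for i, eid in enumerate(gl.graph.black_ids()):
        lab.edge[eid] = i % 4
    gl = LabeledGraph(gl.graph, lab)
    rho = parsimonious_scenario(gl.graph)
    scen, state = _lift(gl, rho, lambda x, y: (x + y, 0))
    res = model.settle(settle_groups(state))
    assert res is not None
    _, changes = res
    scen.steps.extend(OChange(e, v) for e, v in changes)
    c, k = validate_and_cost(gl, scen, model)
    assert k == d2b(gl.graph)


def test_indicator_cost_counts_mixed_breaks():
    # the indicator table prices a scenario by its label-mixing 2-breaks
    gl, _, bg = random_instance(GeneratorConfig(n=3, k=2, seed=9, labels=("x", "y")))
    model = model_phi_f(PhiMatrix.indicator(("x", "y")))
    rho = parsimonious_scenario(gl.graph)
    scen, state = _lift(gl, rho, lambda x, y: (x, y))
    _, changes = model.settle(settle_groups(state))
    scen.steps.extend(OChange(e, lab) for e, lab in changes)
    cost, _ = validate_and_cost(gl, scen, model)
    mixed = []
    replay(gl, scen, model=None, on_break=lambda i, a, b, x, y: mixed.append(x != y))
    assert cost == sum(mixed)


def test_scenario_jsonl_round_trip():
    scen = OScenario(
        [
            OBreak(0, 2, 1, 0, "x", "y", 10, 11, 0.5),
            OChange(10, TAU, 0.0),
        ]
    )
    back = OScenario.from_jsonl(scen.to_jsonl())
    assert back.steps == scen.steps
    assert back.two_break_length == 1
    assert back.cost == 0.5
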