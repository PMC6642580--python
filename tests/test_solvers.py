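"""Planar-tree DP, scenario extraction, and the solving pipeline."""

import math

import numpy as np
import pytest

from mcps.colored_graphs import GRAY, TAU, LabeledGraph, Labeling, build_breakpoint_graph
from mcps.cost_models import PhiMatrix, model_phi_f, model_phi_l, validate_and_cost
from mcps.genomes import Genome
from mcps.solvers import (
    ApproximateCircleSolver,
    BruteForceCircleSolver,
    PlanarTree,
    PlanarTreeCircleSolver,
    approx_solve_breakpoint_graph,
    brute_force_mcps,
    enumerate_planar_trees,
    min_cost_planar_tree,
    scenario_from_tree,
    solve_breakpoint_graph,
    solve_circle_phi_f,
    solve_general_ilp,
    solve_simple_cycle,
    tree_of_scenario,
)
from mcps.synthetic import GeneratorConfig, random_instance, random_phi
from conftest import make_circle


def test_planar_tree_dp_base_cases():
    phi = PhiMatrix.from_array(("x", "y"), [[0.0, 2.5], [2.5, 0.0]])
    t = min_cost_planar_tree(("x", "y"), phi)
    assert t.edges == ((0, 1),) and t.cost == 2.5
    ones = min_cost_planar_tree(tuple("abcde"), lambda x, y: 1.0)
    assert ones.cost == 4.0 and ones.is_spanning_tree() and ones.is_noncrossing()


@pytest.mark.parametrize("r", [3, 4, 5])
def test_planar_tree_dp_matches_exhaustive(r):
    labels = tuple(range(r))
    trees = list(enumerate_planar_trees(r))
    for seed in range(10):
        phi = random_phi(labels, seed=seed)
        t = min_cost_planar_tree(labels, phi)
        best = min(sum(phi(a, b) for a, b in cand.edges) for cand in trees)
        assert t.cost == pytest.approx(best)
        assert t.is_spanning_tree() and t.is_noncrossing()
        assert t.cost == pytest.approx(sum(phi(t.order[a], t.order[b]) for a, b in t.edges))


def test_planar_tree_rotation_invariance():
    labels = ("u", "v", "w", "x")
    phi = random_phi(labels, seed=3)
    base = min_cost_planar_tree(labels, phi).cost
    for shift in range(1, 4):
        rotated = labels[shift:] + labels[:shift]
        assert min_cost_planar_tree(rotated, phi).cost == pytest.approx(base)


def test_scenario_from_star_tree():
    labels = ("c", "l1", "l2")
    phi = PhiMatrix.from_dict(
        {("c", "l1"): 2.0, ("c", "l2"): 3.0, ("l1", "l2"): 9.0, ("c", "c"): 0.0, ("l1", "l1"): 0.0, ("l2", "l2"): 0.0}
    )
    model = model_phi_f(phi)
    circle = make_circle(labels)
    star = PlanarTree(labels, ((0, 1), (0, 2)), 5.0)
    scen = scenario_from_tree(circle, star, model)
    cost, breaks = validate_and_cost(circle, scen, model)
    assert breaks == 2 and cost == pytest.approx(5.0)
    assert set(tree_of_scenario(circle, scen).edges) == {(0, 1), (0, 2)}


def test_tree_of_empty_scenario_single_edge_circle():
    circle = make_circle(("x",))
    from mcps.cost_models import OScenario

    t = tree_of_scenario(circle, OScenario([]))
    assert t.edges == () and t.order == ("x",)


@pytest.mark.parametrize("r", [1, 2, 3, 4])
def test_circle_solver_matches_brute_force(r):
    for seed in range(5):
        rng = np.random.default_rng(1000 * r + seed)
        alphabet = ("x", "y", "z")
        labels = tuple(alphabet[i] for i in rng.integers(0, 3, size=r))
        model = model_phi_f(random_phi(alphabet, seed=seed))
        circle = make_circle(labels)
        a = solve_circle_phi_f(circle, model)
        b = brute_force_mcps(circle, model, limit=6)
        assert a.mcps == pytest.approx(b.mcps)
        cost, breaks = validate_and_cost(circle, a.scenario, model)
        assert cost == pytest.approx(a.mcps) and breaks == a.d2b == r - 1


def test_duplicate_labels_same_as_relabeled():
    # duplicated labels reuse the same table rows (hat-relabel argument)
    alphabet = ("x", "y")
    model = model_phi_f(random_phi(alphabet, seed=7))
    dup = make_circle(("x", "y", "x", "x"))
    res = solve_circle_phi_f(dup, model)
    oracle = brute_force_mcps(dup, model, limit=6)
    assert res.mcps == pytest.approx(oracle.mcps)


def test_solve_simple_cycle_on_fixtures(fx):
    alphabet = ("x", "y")
    model = model_phi_f(random_phi(alphabet, seed=2))
    for name in ("loop_split_cycle", "plain_split_cycle"):
        s = fx[name].copy()
        for i, eid in enumerate(s.graph.black_ids()):
            s.labeling.edge[eid] = alphabet[i % 2]
        res = solve_simple_cycle(s, PlanarTreeCircleSolver(model))
        oracle = brute_force_mcps(s, model, limit=6)
        assert res.mcps == pytest.approx(oracle.mcps)
        cost, breaks = validate_and_cost(s, res.scenario, model)
        assert cost == pytest.approx(res.mcps) and breaks == res.d2b


def test_solve_breakpoint_identity_is_free():
    b = Genome.from_orders([1, 2, -3])
    g = build_breakpoint_graph(b, b).graph
    lab = Labeling()
    for eid in g.black_ids():
        lab.edge[eid] = "x"
    model = model_phi_f(PhiMatrix.constant(("x",), 1.0))
    res = solve_breakpoint_graph(LabeledGraph(g, lab), PlanarTreeCircleSolver(model))
    assert res.mcps == 0.0 and res.d2b == 0


def test_solve_breakpoint_constant_phi_equals_distance(fx):
    a, b = fx["reversal_pair"]
    g = build_breakpoint_graph(a, b).graph
    lab = Labeling()
    for eid in g.black_ids():
        lab.edge[eid] = "x"
    model = model_phi_f(PhiMatrix.constant(("x",), 1.0))
    res = solve_breakpoint_graph(LabeledGraph(g, lab), PlanarTreeCircleSolver(model))
    assert res.mcps == pytest.approx(1.0)
    assert res.d2b == 1


@pytest.mark.parametrize("seed", range(10))
def test_solve_breakpoint_matches_brute_force(seed):
    gl, model, _ = random_instance(GeneratorConfig(n=3, k=3, circular=bool(seed % 2), seed=400 + seed))
    res = solve_breakpoint_graph(gl, PlanarTreeCircleSolver(model))
    oracle = brute_force_mcps(gl, model, limit=8)
    assert res.mcps == pytest.approx(oracle.mcps)


def test_monotonicity_under_constant_shift():
    gl, model, _ = random_instance(GeneratorConfig(n=3, k=3, seed=77))
    base = solve_breakpoint_graph(gl, PlanarTreeCircleSolver(model))
    shifted_model = model_phi_f(model.phi.shifted(0.75))
    shifted = solve_breakpoint_graph(gl, PlanarTreeCircleSolver(shifted_model))
    assert shifted.mcps == pytest.approx(base.mcps + 0.75 * base.d2b)


def test_phi_l_sum_difference_lower_bound():
    # a single circle: total black length vs gray length must be bridged
    circle = make_circle((5, 1, 4), gray_labels=(0, 2, 1))
    model = model_phi_l()
    res = brute_force_mcps(circle, model, limit=6)
    b_sum, g_sum = 5 + 1 + 4, 0 + 2 + 1
    assert res.mcps >= abs(b_sum - g_sum)
    cost, breaks = validate_and_cost(circle, res.scenario, model)
    assert cost == pytest.approx(res.mcps) and breaks == 2


def test_phi_l_through_matching_pipeline():
    gl, _, _ = random_instance(GeneratorConfig(n=3, k=3, seed=5))
    model = model_phi_l()
    lab = Labeling(default_edge=0)
    for i, eid in enumerate(gl.graph.black_ids()):
        lab.edge[eid] = (3 * i) % 5
    gl = LabeledGraph(gl.graph, lab)
    res = solve_breakpoint_graph(gl, BruteForceCircleSolver(model, limit=8))
    oracle = brute_force_mcps(gl, model, limit=8)
    assert res.mcps == pytest.approx(oracle.mcps)
    cost, breaks = validate_and_cost(gl, res.scenario, model)
    assert cost == pytest.approx(res.mcps) and breaks == res.d2b


def test_ilp_on_disjoint_circles():
    alphabet = ("x", "y")
    model = model_phi_f(random_phi(alphabet, seed=1))
    c1 = make_circle(("x", "y"))
    c2 = make_circle(("y", "y"))
    # embed the two circles in one graph on disjoint vertices
    from mcps.colored_graphs import BLACK, ColoredGraph

    g = ColoredGraph()
    lab = Labeling()
    for offset, circle in ((0, c1), (100, c2)):
        for eid in sorted(circle.graph.edges):
            e = circle.graph.edges[eid]
            new = g.add_edge(e.color, (offset, e.u), (offset, e.v))
            if e.color == BLACK:
                lab.edge[new] = circle.el(eid)
    gl = LabeledGraph(g, lab)
    res = solve_general_ilp(gl, PlanarTreeCircleSolver(model), cycle_limit=8)
    direct = sum(
        solve_circle_phi_f(c, model).mcps for c in (c1, c2)
    )
    assert res.mcps == pytest.approx(direct)
    assert res.details["c"] == 2


def test_approx_alpha_one_is_exact():
    gl, model, _ = random_instance(GeneratorConfig(n=3, k=3, seed=12))
    exact = solve_breakpoint_graph(gl, PlanarTreeCircleSolver(model))
    same = approx_solve_breakpoint_graph(gl, ApproximateCircleSolver(model, alpha=1.0))
    assert same.mcps == pytest.approx(exact.mcps)


@pytest.mark.parametrize("seed", range(6))
def test_approx_never_below_exact(seed):
    gl, model, _ = random_instance(GeneratorConfig(n=3, k=3, seed=600 + seed))
    exact = solve_breakpoint_graph(gl, PlanarTreeCircleSolver(model))
    approx = approx_solve_breakpoint_graph(gl, ApproximateCircleSolver(model, alpha=1.5))
    assert approx.mcps >= exact.mcps - 1e-9
    assert approx.mcps <= 1.5 * exact.mcps + 1e-9
    cost, breaks = validate_and_cost(gl, approx.scenario, model)
    assert cost == pytest.approx(approx.mcps) and breaks == approx.d2b
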