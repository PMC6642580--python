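"""Operation sets, cost functions, and labeled-scenario validation.

A labeled graph can be transformed by *edge-label changes* and by
*2-breaks on labels*; an operation set decides which of those moves are
members, and a cost function prices each member.  An O-scenario is a
sequence of member moves after which the graph is terminal with equal
black and gray *labeled* edge multisets; its 2-break-length counts only
the 2-breaks.  The minimum cost among O-scenarios whose 2-break-length
equals the unconstrained minimum e(G) - c(G) is the MCPS value; when no
such scenario exists the value is infinite.

Operation sets are intensional (membership predicates), never
materialized: the intergene-length set, for instance, is infinite.
Built-in models:

* ``model_phi_f`` -- fixed edge labels ("colors"); a 2-break keeps its
  two labels and costs a symmetric table value Phi(x, y); relabeling to
  the terminal label tau is free.  The indicator table reproduces the
  minimum local parsimonious scenario model.
* ``model_hic`` -- the Hi-C weighting: cost Phi_max - Phi_HiC(x, y),
  so maximizing physical-proximity weight is a minimization.
* ``model_phi_l`` -- intergene lengths: a 2-break must conserve the sum
  of its two labels (w1 + w2 = w3 + w4) and is free; a label change
  (an indel) costs |w1 - w2|.
* ``model_vertex`` -- a single edge label; the cost of a 2-break is an
  arbitrary function of the four participating vertex labels.
"""

from __future__ import annotations

import json
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .colored_graphs import BLACK, GRAY, TAU, LabeledGraph, is_terminal
from .scenarios import TwoBreak, apply_two_break

__all__ = [
    "TAU",
    "PhiMatrix",
    "CostModel",
    "PhiFModel",
    "PhiLModel",
    "VertexModel",
    "model_phi_f",
    "model_hic",
    "model_phi_l",
    "model_vertex",
    "OBreak",
    "OChange",
    "OScenario",
    "ScenarioError",
    "lift_scenario",
    "replay",
    "settle_groups",
    "validate_and_cost",
]

INF = math.inf


@dataclass(frozen=True)
class PhiMatrix:
    """A symmetric nonnegative cost table over edge labels."""

    labels: tuple
    values: tuple  # row-major tuple of tuples

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (len(self.labels), len(self.labels)):
            raise ValueError("Phi must be square over its labels")
        if not np.allclose(arr, arr.T):
            raise ValueError("Phi must be symmetric")
        if (arr < 0).any():
            raise ValueError("Phi must be nonnegative")

    @classmethod
    def from_array(cls, labels: Sequence, array) -> "PhiMatrix":
        arr = np.asarray(array, dtype=float)
        return cls(tuple(labels), tuple(tuple(row) for row in arr))

    @classmethod
    def from_dict(cls, entries: dict) -> "PhiMatrix":
        labels = sorted({l for pair in entries for l in pair}, key=str)
        idx = {l: i for i, l in enumerate(labels)}
        arr = np.zeros((len(labels), len(labels)))
        for (x, y), v in entries.items():
            arr[idx[x], idx[y]] = v
            arr[idx[y], idx[x]] = v
        return cls.from_array(labels, arr)

    @classmethod
    def constant(cls, labels: Sequence, value: float) -> "PhiMatrix":
        k = len(labels)
        return cls.from_array(labels, np.full((k, k), float(value)))

    @classmethod
    def indicator(cls, labels: Sequence) -> "PhiMatrix":
        k = len(labels)
        return cls.from_array(labels, 1.0 - np.eye(k))

    def __contains__(self, label) -> bool:
        return label in self.labels

    def __call__(self, x, y) -> float:
        try:
            return self.values[self.labels.index(x)][self.labels.index(y)]
        except ValueError:
            return INF

    def shifted(self, delta: float) -> "PhiMatrix":
        arr = np.asarray(self.values) + delta
        return PhiMatrix.from_array(self.labels, arr)

    @classmethod
    def read_tsv(cls, path) -> "PhiMatrix":
        with open(path, encoding="utf-8") as fh:
            rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
        labels = rows[0][1:]
        arr = [[float(x) for x in row[1:]] for row in rows[1:]]
        return cls.from_array(labels, arr)

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t" + "\t".join(map(str, self.labels)) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(str(lab) + "\t" + "\t".join(f"{v:g}" for v in row) + "\n")


class CostModel:
    """Membership contracts and costs for O-changes and O-breaks.

    The membership predicates take the full label context: an O-change
    ``(({a,b},x);({a,b},y))`` and an O-break
    ``(({a,b},x),({c,d},y);({a,c},z),({b,d},t))``.  The solver-facing
    hooks (`break_options`, `settle`) enumerate the finitely many
    relevant member moves; all built-in models allow deferring every
    label change to the end of a scenario at no extra cost, which is
    what makes the hooks sufficient.
    """

    name = "abstract"

    # -- membership / cost contracts (constant time) --------------------
    def is_change(self, a, b, x, y) -> bool:
        raise NotImplementedError

    def change_cost(self, a, b, x, y) -> float:
        raise NotImplementedError

    def is_break(self, a, b, c, d, x, y, z, t) -> bool:
        raise NotImplementedError

    def break_cost(self, a, b, c, d, x, y, z, t) -> float:
        raise NotImplementedError

    # -- solver hooks ----------------------------------------------------
    def break_options(self, a, b, c, d, x, y) -> list[tuple[tuple, float]]:
        """Member product labelings ((z, t), cost) for the given context."""
        raise NotImplementedError

    def settle(self, groups: list[tuple[list[tuple[int, object]], list[tuple[int, object]]]]):
        """Minimum-cost label changes finishing a terminal graph.

        ``groups`` lists, per endpoint pair, the black edges (id, label)
        and the gray edges (id, label).  Returns
        (cost, [(edge id, new label), ...]) or None when the labeled
        multisets cannot be equalized with member changes.
        """
        raise NotImplementedError


class PhiFModel(CostModel):
    """Fixed labels: 2-breaks keep their labels and cost Phi(x, y)."""

    name = "phi_f"

    def __init__(self, phi: PhiMatrix, tau=TAU):
        self.phi = phi
        self.tau = tau
        if tau in phi.labels:
            raise ValueError("the terminal label is not a 2-break color")

    def is_change(self, a, b, x, y) -> bool:
        return y == self.tau and x in self.phi.labels

    def change_cost(self, a, b, x, y) -> float:
        return 0.0 if self.is_change(a, b, x, y) else INF

    def is_break(self, a, b, c, d, x, y, z, t) -> bool:
        return x in self.phi.labels and y in self.phi.labels and ((z, t) == (x, y) or (z, t) == (y, x))

    def break_cost(self, a, b, c, d, x, y, z, t) -> float:
        return self.phi(x, y) if self.is_break(a, b, c, d, x, y, z, t) else INF

    def break_options(self, a, b, c, d, x, y):
        if x not in self.phi.labels or y not in self.phi.labels:
            return []
        cost = self.phi(x, y)
        opts = [((x, y), cost)]
        if x != y:
            opts.append(((y, x), cost))
        return opts

    def settle(self, groups):
        # Label changes all target tau and are free, so the cheapest finish
        # relabels every non-tau edge (black or gray) to tau; a label
        # outside the table has no member change and must already match.
        changes: list[tuple[int, object]] = []
        for blacks, grays in groups:
            stuck_black = Counter()
            stuck_gray = Counter()
            for side, stuck in ((blacks, stuck_black), (grays, stuck_gray)):
                for eid, lab in side:
                    if lab == self.tau:
                        continue
                    if lab in self.phi.labels:
                        changes.append((eid, self.tau))
                    else:
                        stuck[lab] += 1
            if stuck_black != stuck_gray:
                return None
        return 0.0, changes


def model_phi_f(phi: PhiMatrix, tau=TAU) -> PhiFModel:
    return PhiFModel(phi, tau)


def model_hic(intervals: dict, hic_values: dict | PhiMatrix, tau=TAU) -> PhiFModel:
    """Hi-C weighting: cost of a 2-break is Phi_max - Phi_HiC(x, y).

    ``intervals`` maps edges (or adjacencies) to their genomic-interval
    labels; ``hic_values`` gives the averaged Hi-C contact value per
    unordered label pair.
    """
    if isinstance(hic_values, PhiMatrix):
        hic = hic_values
    else:
        hic = PhiMatrix.from_dict(hic_values)
    for label in set(intervals.values()):
        if label not in hic.labels:
            raise ValueError(f"interval label {label!r} missing from the Hi-C table")
    arr = np.asarray(hic.values, dtype=float)
    phi = PhiMatrix.from_array(hic.labels, arr.max() - arr)
    return PhiFModel(phi, tau)


class PhiLModel(CostModel):
    """Intergene lengths: sum-conserving free 2-breaks, indels cost |delta|."""

    name = "phi_l"

    def _nat(self, *ws) -> bool:
        return all(isinstance(w, (int, np.integer)) and not isinstance(w, bool) and w >= 0 for w in ws)

    def is_change(self, a, b, x, y) -> bool:
        return self._nat(x, y)

    def change_cost(self, a, b, x, y) -> float:
        return float(abs(x - y)) if self.is_change(a, b, x, y) else INF

    def is_break(self, a, b, c, d, x, y, z, t) -> bool:
        return self._nat(x, y, z, t) and x + y == z + t

    def break_cost(self, a, b, c, d, x, y, z, t) -> float:
        return 0.0 if self.is_break(a, b, c, d, x, y, z, t) else INF

    def break_options(self, a, b, c, d, x, y):
        if not self._nat(x, y):
            return []
        s = int(x) + int(y)
        return [((z, s - z), 0.0) for z in range(s + 1)]

    def settle(self, groups):
        cost = 0.0
        changes: list[tuple[int, object]] = []
        for blacks, grays in groups:
            if len(blacks) != len(grays):
                return None
            bs = sorted(blacks, key=lambda p: p[1])
            gs = sorted(lab for _, lab in grays)
            for (eid, bl), gl in zip(bs, gs):
                cost += abs(bl - gl)
                if bl != gl:
                    changes.append((eid, gl))
        return cost, changes


def model_phi_l() -> PhiLModel:
    return PhiLModel()


class VertexModel(CostModel):
    """Single edge label; 2-break cost depends on the four vertex labels."""

    name = "vertex"

    def __init__(self, cost_fn: Callable, tau=TAU):
        import inspect

        params = [
            p
            for p in inspect.signature(cost_fn).parameters.values()
            if p.kind in (p.POSITIONAL_ONLY, p.POSITIONAL_OR_KEYWORD)
        ]
        if len(params) != 4:
            raise ValueError("vertex cost function must take the 4 vertex labels (a, b, c, d)")
        self.cost_fn = cost_fn
        self.tau = tau

    def is_change(self, a, b, x, y) -> bool:
        return False

    def change_cost(self, a, b, x, y) -> float:
        return INF

    def is_break(self, a, b, c, d, x, y, z, t) -> bool:
        return x == y == z == t == self.tau

    def break_cost(self, a, b, c, d, x, y, z, t) -> float:
        return float(self.cost_fn(a, b, c, d)) if self.is_break(a, b, c, d, x, y, z, t) else INF

    def break_options(self, a, b, c, d, x, y):
        if x != self.tau or y != self.tau:
            return []
        return [((self.tau, self.tau), float(self.cost_fn(a, b, c, d)))]

    def settle(self, groups):
        for blacks, grays in groups:
            if Counter(lab for _, lab in blacks) != Counter(lab for _, lab in grays):
                return None
        return 0.0, []


def model_vertex(cost_fn: Callable, tau=TAU) -> VertexModel:
    return VertexModel(cost_fn, tau)


# ---------------------------------------------------------------------------
# O-scenarios: steps, replay, validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OBreak:
    """An O-break: 2-break (e1,s1)x(e2,s2) with product labels z, t.

    ``p1`` and ``p2`` are scenario-local ids for the two product edges
    (the first pairs dart (e1, s1) with (e2, s2) and is labeled ``z``);
    later steps may reference them.  Real edge ids are assigned at
    replay time through a translation table.
    """

    e1: int
    e2: int
    s1: int
    s2: int
    z: object
    t: object
    p1: int
    p2: int
    cost: float = 0.0


@dataclass(frozen=True)
class OChange:
    e: int
    y: object
    cost: float = 0.0


@dataclass
class OScenario:
    steps: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def two_break_length(self) -> int:
        return sum(1 for s in self.steps if isinstance(s, OBreak))

    @property
    def cost(self) -> float:
        return float(sum(s.cost for s in self.steps))

    def renumbered(self, start: int, keep: set | None = None) -> tuple["OScenario", int]:
        """Remap scenario-local product ids into [start, ...).

        Ids in ``keep`` (edge ids of the initial graph) are untouched.
        Returns the new scenario and the next free id.
        """
        keep = keep or set()
        mapping: dict[int, int] = {}
        nxt = start

        def m(eid: int, fresh: bool) -> int:
            nonlocal nxt
            if eid in mapping:
                return mapping[eid]
            if not fresh:
                return eid
            mapping[eid] = nxt
            nxt += 1
            return mapping[eid]

        steps = []
        for s in self.steps:
            if isinstance(s, OBreak):
                steps.append(
                    OBreak(m(s.e1, False), m(s.e2, False), s.s1, s.s2, s.z, s.t, m(s.p1, True), m(s.p2, True), s.cost)
                )
            else:
                steps.append(OChange(m(s.e, False), s.y, s.cost))
        return OScenario(steps), nxt

    @staticmethod
    def concat(parts: Iterable["OScenario"], start: int) -> "OScenario":
        steps: list = []
        nxt = start
        for part in parts:
            renum, nxt = part.renumbered(nxt)
            steps.extend(renum.steps)
        return OScenario(steps)

    # -- serialization: JSON lines, one step per line -------------------
    def to_jsonl(self) -> str:
        lines = []
        for i, s in enumerate(self.steps):
            if isinstance(s, OBreak):
                rec = {
                    "step": i,
                    "kind": "break",
                    "edges": [s.e1, s.e2],
                    "sides": [s.s1, s.s2],
                    "products": [s.p1, s.p2],
                    "labels": [_jsonable(s.z), _jsonable(s.t)],
                    "cost": s.cost,
                }
            else:
                rec = {"step": i, "kind": "change", "edge": s.e, "label": _jsonable(s.y), "cost": s.cost}
            lines.append(json.dumps(rec, sort_keys=True))
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_jsonl(cls, text: str) -> "OScenario":
        steps: list = []
        for line in text.splitlines():
            if not line.strip():
                continue
            rec = json.loads(line)
            if rec["kind"] == "break":
                steps.append(
                    OBreak(
                        rec["edges"][0],
                        rec["edges"][1],
                        rec["sides"][0],
                        rec["sides"][1],
                        rec["labels"][0],
                        rec["labels"][1],
                        rec["products"][0],
                        rec["products"][1],
                        rec.get("cost", 0.0),
                    )
                )
            else:
                steps.append(OChange(rec["edge"], rec["label"], rec.get("cost", 0.0)))
        return cls(steps)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    return x


class ScenarioError(ValueError):
    def __init__(self, step: int, reason: str):
        super().__init__(f"invalid O-scenario at step {step}: {reason}")
        self.step = step
        self.reason = reason


def labeled_terminal(gl: LabeledGraph) -> bool:
    """Terminal graph whose black and gray labeled edge multisets agree."""
    black = Counter((e.pair(), gl.el(eid)) for eid, e in gl.graph.edges.items() if e.color == BLACK)
    gray = Counter((e.pair(), gl.el(eid)) for eid, e in gl.graph.edges.items() if e.color == GRAY)
    return black == gray


def replay(
    gl: LabeledGraph,
    scenario: OScenario,
    model: CostModel | None = None,
    on_break=None,
) -> tuple[LabeledGraph, float, int]:
    """Replay an O-scenario on a copy of ``gl``.

    With a model, membership of every step is checked and costs are
    recomputed; without one, labels are just tracked.  Returns the final
    labeled graph, the total cost, and the 2-break-length.
    """
    state = gl.copy()
    real: dict[int, int] = {}

    def rid(eid: int) -> int:
        return real.get(eid, eid)

    cost = 0.0
    breaks = 0
    for i, step in enumerate(scenario.steps):
        if isinstance(step, OBreak):
            a_id, b_id = rid(step.e1), rid(step.e2)
            for eid in (a_id, b_id):
                if eid not in state.graph.edges:
                    raise ScenarioError(i, f"operand edge {eid} absent")
                if state.graph.edges[eid].color != BLACK:
                    raise ScenarioError(i, f"operand edge {eid} is not black")
            e1, e2 = state.graph.edges[a_id], state.graph.edges[b_id]
            x, y = state.el(a_id), state.el(b_id)
            a = state.vl(e1.endpoint(step.s1))
            b = state.vl(e1.endpoint(1 - step.s1))
            c = state.vl(e2.endpoint(step.s2))
            d = state.vl(e2.endpoint(1 - step.s2))
            if model is not None:
                if not model.is_break(a, b, c, d, x, y, step.z, step.t):
                    raise ScenarioError(i, f"2-break on labels ({x},{y})->({step.z},{step.t}) not a member")
                cost += model.break_cost(a, b, c, d, x, y, step.z, step.t)
            if on_break is not None:
                on_break(i, a_id, b_id, x, y)
            g2, (f1, f2) = apply_two_break(state.graph, TwoBreak(a_id, b_id, step.s1, step.s2))
            state.graph = g2
            state.labeling.edge.pop(a_id, None)
            state.labeling.edge.pop(b_id, None)
            state.labeling.edge[f1] = step.z
            state.labeling.edge[f2] = step.t
            real[step.p1] = f1
            real[step.p2] = f2
            breaks += 1
        else:
            eid = rid(step.e)
            if eid not in state.graph.edges:
                raise ScenarioError(i, f"edge {eid} absent")
            e = state.graph.edges[eid]
            x = state.el(eid)
            if model is not None:
                if not model.is_change(state.vl(e.u), state.vl(e.v), x, step.y):
                    raise ScenarioError(i, f"label change {x}->{step.y} not a member")
                cost += model.change_cost(state.vl(e.u), state.vl(e.v), x, step.y)
            state.labeling.edge[eid] = step.y
    return state, cost, breaks


def validate_and_cost(gl: LabeledGraph, scenario: OScenario, model: CostModel) -> tuple[float, int]:
    """Replay, check membership and the labeled-terminal end condition.

    Returns (total cost, 2-break-length); raises :class:`ScenarioError`
    with the offending step index otherwise.
    """
    state, cost, breaks = replay(gl, scenario, model)
    if not is_terminal(state.graph):
        raise ScenarioError(len(scenario.steps), "final graph is not terminal")
    if not labeled_terminal(state):
        raise ScenarioError(len(scenario.steps), "non-terminal labels: black and gray labeled multisets differ")
    return cost, breaks


def lift_scenario(gl: LabeledGraph, rho, products=lambda x, y: (x, y), model: CostModel | None = None) -> OScenario:
    """Lift a graph-level 2-break scenario into an O-scenario.

    ``products`` maps the operand labels (x, y) to the product labels
    (z, t); the default keeps labels fixed.  Settling label changes are
    appended when a model is given (this is the constructive form of
    p-sufficiency for the built-in models: any parsimonious 2-break
    scenario lifts to an O-scenario of the same 2-break-length).
    """
    steps: list = []
    state = gl.copy()
    real: dict[int, int] = {}
    for tb in rho:
        e1 = real.get(tb.e1, tb.e1)
        e2 = real.get(tb.e2, tb.e2)
        x, y = state.el(e1), state.el(e2)
        z, t = products(x, y)
        g2, (f1, f2) = apply_two_break(state.graph, TwoBreak(e1, e2, tb.s1, tb.s2))
        state.graph = g2
        state.labeling.edge.pop(e1, None)
        state.labeling.edge.pop(e2, None)
        state.labeling.edge[f1] = z
        state.labeling.edge[f2] = t
        steps.append(OBreak(e1, e2, tb.s1, tb.s2, z, t, f1, f2))
        if tb.p1 is not None:
            real[tb.p1] = f1
            real[tb.p2] = f2
    if model is not None:
        res = model.settle(settle_groups(state))
        if res is None:
            raise ValueError("labels cannot be settled with member changes")
        _, changes = res
        steps.extend(OChange(e, lab) for e, lab in changes)
    return OScenario(steps)


def settle_groups(gl: LabeledGraph) -> list[tuple[list[tuple[int, object]], list[tuple[int, object]]]]:
    """Group a terminal graph's edges by endpoints for CostModel.settle."""
    groups: dict[tuple, tuple[list, list]] = defaultdict(lambda: ([], []))
    for eid in sorted(gl.graph.edges):
        e = gl.graph.edges[eid]
        blacks, grays = groups[e.pair()]
        (blacks if e.color == BLACK else grays).append((eid, gl.el(eid)))
    return [groups[k] for k in sorted(groups, key=str)]
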