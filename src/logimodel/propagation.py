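"""Value propagation (percolation) of clamped components, and differential
comparison of two propagation analyses.

Clamping fixes components at constant levels (modelling persistent inputs,
knockouts or ectopic expression); the clamp overrides the component's own
rule.  Each clamped value is substituted into the rules of the component's
targets, the rules are simplified, and any rule that becomes constant
freezes its component, whose value is propagated in turn, until quiescence.
The frozen assignment splits the model into components constrained by the
context and components that keep some degree of freedom, and two contexts
can be compared component by component.
"""

from __future__ import annotations

import random
from collections import deque
from dataclasses import dataclass
from itertools import product
from typing import Dict, List, Mapping, Optional, Tuple, Union

from .model_core import (
    And,
    Atom,
    Const,
    Expr,
    LogicalFunction,
    LogicalModel,
    ModelError,
    Not,
    Or,
    PartialAssignment,
)

__all__ = [
    "Constant",
    "Residual",
    "simplify_under",
    "PropagationResult",
    "propagate",
    "tally",
    "DifferentialClassification",
    "compare_propagations",
    "export_annotated_graph",
    "CATEGORY_COLORS",
]


@dataclass(frozen=True)
class Constant:
    """Outcome of simplification: the rule is fixed at ``level``."""

    level: int


@dataclass(frozen=True)
class Residual:
    """Outcome of simplification: a constant-folded but non-constant rule."""

    function: LogicalFunction


# ---------------------------------------------------------------------------
# Constant folding and simplification
# ---------------------------------------------------------------------------

def _fold(expr: Expr, assignment: Mapping[str, int]) -> Expr:
    """Replace atoms on assigned components by constants and fold."""
    if isinstance(expr, Const):
        return expr
    if isinstance(expr, Atom):
        if expr.component in assignment:
            return Const(1 if assignment[expr.component] >= expr.threshold else 0)
        return expr
    if isinstance(expr, Not):
        child = _fold(expr.child, assignment)
        if isinstance(child, Const):
            return Const(1 - child.value)
        return Not(child)
    if isinstance(expr, (And, Or)):
        is_and = isinstance(expr, And)
        absorbing = 0 if is_and else 1
        children: List[Expr] = []
        for c in expr.children:
            folded = _fold(c, assignment)
            if isinstance(folded, Const):
                if folded.value == absorbing:
                    return Const(absorbing)
                continue  # neutral element, drop
            children.append(folded)
        if not children:
            return Const(1 - absorbing)
        if len(children) == 1:
            return children[0]
        return And(tuple(children)) if is_and else Or(tuple(children))
    raise ModelError(f"unknown expression node {expr!r}")


def simplify_under(
    model: LogicalModel,
    f: LogicalFunction,
    assignment: PartialAssignment,
) -> Union[Constant, Residual]:
    """Simplify a rule under a partial assignment of its regulators.

    Atoms on assigned components are replaced by constants and the
    expression folded.  The rule is declared ``Constant(v)`` iff it
    evaluates to ``v`` for *every* combination of the remaining free
    regulators — decided by exhaustive evaluation over those regulators, so
    the constancy test is complete rather than merely syntactic.  Otherwise
    the constant-folded residual is returned (dropping cases whose folded
    condition is the constant 0).
    """
    model.check_assignment(assignment)
    folded_cases: List[Tuple[Expr, int]] = []
    for condition, level in f.cases:
        folded = _fold(condition, assignment)
        if isinstance(folded, Const) and folded.value == 0:
            continue
        folded_cases.append((folded, level))
        if isinstance(folded, Const):  # condition always true: later cases dead
            break

    residual = LogicalFunction(tuple(folded_cases))
    free_regs = sorted(residual.regulators())
    ranges = [range(model.max_level(r) + 1) for r in free_regs]
    value: Optional[int] = None
    for combo in product(*ranges):
        local = dict(zip(free_regs, combo))
        v = residual.target(local)
        if value is None:
            value = v
        elif v != value:
            return Residual(residual)
    assert value is not None
    return Constant(value)


# ---------------------------------------------------------------------------
# Propagation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PropagationResult:
    """Outcome of percolating a clamp set through a model.

    ``frozen`` contains the clamps plus every component whose rule
    percolated to a constant.  ``residuals`` carries the simplified rules of
    the remaining non-input free components; unclamped inputs are listed in
    ``free_inputs`` (their identity rule never freezes).
    """

    model: LogicalModel
    clamps: PartialAssignment
    frozen: PartialAssignment
    residuals: Dict[str, LogicalFunction]

    @property
    def free_inputs(self) -> List[str]:
        return [
            c.name
            for c in self.model.components
            if self.model.is_input(c.name) and c.name not in self.frozen
        ]

    def status(self, name: str) -> str:
        """``frozen``, ``free`` or ``input`` (unclamped input)."""
        if name in self.frozen:
            return "frozen"
        if self.model.is_input(name):
            return "input"
        return "free"


def propagate(
    model: LogicalModel,
    clamps: PartialAssignment,
    rng: Optional[random.Random] = None,
) -> PropagationResult:
    """Percolate ``clamps`` to a fixpoint.

    Worklist algorithm: whenever the rule of a free component simplifies to
    a constant under the current frozen assignment, the component freezes at
    that value and its targets are re-examined.  Clamped components keep
    their clamped value throughout (the clamp overrides the rule), so the
    frozen set always contains the clamps.  Each component freezes at most
    once, so the loop terminates, and the result is independent of worklist
    order (``rng``, used only to shuffle the worklist, exists to let tests
    exercise that confluence).
    """
    model.check_assignment(clamps)
    frozen: Dict[str, int] = dict(clamps)
    worklist = deque(c.name for c in model.components if c.name not in frozen)
    pending = set(worklist)
    while worklist:
        if rng is not None:
            order = list(worklist)
            rng.shuffle(order)
            worklist = deque(order)
        name = worklist.popleft()
        pending.discard(name)
        if name in frozen:
            continue
        outcome = simplify_under(model, model.functions[name], frozen)
        if isinstance(outcome, Constant):
            frozen[name] = outcome.level
            for target in model.targets(name):
                if target not in frozen and target not in pending:
                    worklist.append(target)
                    pending.add(target)

    residuals = {
        c.name: _residual_function(model, c.name, frozen)
        for c in model.components
        if c.name not in frozen and not model.is_input(c.name)
    }
    return PropagationResult(model, dict(clamps), frozen, residuals)


def _residual_function(model: LogicalModel, name: str, frozen: Mapping[str, int]) -> LogicalFunction:
    outcome = simplify_under(model, model.functions[name], dict(frozen))
    assert isinstance(outcome, Residual)
    return outcome.function


def tally(model: LogicalModel, result: PropagationResult) -> Dict[str, int]:
    """Count frozen-inactive / frozen-active / free non-input components.

    Inputs are excluded (an unclamped input trivially stays free; a clamped
    input is part of the imposed context, not an impact of it).  A clamped
    non-input component counts as frozen at its clamped level; frozen-active
    means frozen at level >= 1.
    """
    if result.model is not model:
        raise ModelError("propagation result comes from a different model")
    counts = {"frozen_inactive": 0, "frozen_active": 0, "free": 0}
    for comp in model.components:
        if model.is_input(comp.name):
            continue
        if comp.name in result.frozen:
            if result.frozen[comp.name] >= 1:
                counts["frozen_active"] += 1
            else:
                counts["frozen_inactive"] += 1
        else:
            counts["free"] += 1
    return counts


# ---------------------------------------------------------------------------
# Differential comparison
# ---------------------------------------------------------------------------

CATEGORIES = (
    "input",
    "frozen_off_both",
    "frozen_on_both",
    "frozen_conflict",
    "frozen_off_A_only",
    "frozen_on_A_only",
    "frozen_off_B_only",
    "frozen_on_B_only",
    "free_both",
)

#: Node fill colors for the annotated regulatory graph: inputs gray,
#: frozen-OFF-in-both yellow, frozen-ON-in-both orange, A-only OFF light
#: blue, A-only ON dark blue, B-only frozen green, free white; conflicting
#: frozen values (never observed when one frozen set contains the other) red.
CATEGORY_COLORS = {
    "input": "gray",
    "frozen_off_both": "yellow",
    "frozen_on_both": "orange",
    "frozen_off_A_only": "lightblue",
    "frozen_on_A_only": "darkblue",
    "frozen_off_B_only": "palegreen",
    "frozen_on_B_only": "darkgreen",
    "free_both": "white",
    "frozen_conflict": "red",
}


@dataclass(frozen=True)
class DifferentialClassification:
    """Per-component comparison of two propagation analyses (A vs B)."""

    model: LogicalModel
    categories: Dict[str, str]

    def table(self) -> Dict[str, Dict[str, int]]:
        """3x3 tally: rows frozen_inactive/frozen_active/free, columns A/B/
        intersection, over non-input components.

        The intersection column counts components frozen in *both* analyses
        at the same level (split level 0 vs >= 1) or free in both; mixed
        components (frozen on one side only, or frozen at different levels)
        appear in the A and B columns but in no intersection row.
        """
        rows = {
            "frozen_inactive": {"A": 0, "B": 0, "intersection": 0},
            "frozen_active": {"A": 0, "B": 0, "intersection": 0},
            "free": {"A": 0, "B": 0, "intersection": 0},
        }
        for name, cat in self.categories.items():
            if self.model.is_input(name):
                continue
            if cat in ("frozen_off_both", "frozen_off_A_only"):
                rows["frozen_inactive"]["A"] += 1
            elif cat in ("frozen_on_both", "frozen_on_A_only", "frozen_conflict"):
                rows["frozen_active"]["A"] += 1
            if cat in ("frozen_off_both", "frozen_off_B_only"):
                rows["frozen_inactive"]["B"] += 1
            elif cat in ("frozen_on_both", "frozen_on_B_only", "frozen_conflict"):
                rows["frozen_active"]["B"] += 1
            if cat in ("frozen_off_B_only", "frozen_on_B_only", "free_both"):
                rows["free"]["A"] += 1
            if cat in ("frozen_off_A_only", "frozen_on_A_only", "free_both"):
                rows["free"]["B"] += 1
            if cat == "frozen_off_both":
                rows["frozen_inactive"]["intersection"] += 1
            elif cat == "frozen_on_both":
                rows["frozen_active"]["intersection"] += 1
            elif cat == "free_both":
                rows["free"]["intersection"] += 1
        return rows


def compare_propagations(
    model: LogicalModel,
    result_a: PropagationResult,
    result_b: PropagationResult,
) -> DifferentialClassification:
    """Classify each component by its frozen status in the two analyses.

    A component frozen at level 0 in both analyses is ``frozen_off_both``;
    frozen at the same level >= 1 in both, ``frozen_on_both``; frozen in
    both at different levels, ``frozen_conflict``; frozen on one side only,
    one of the four ``*_only`` categories; free in both, ``free_both``.
    Inputs (unclamped in both analyses) are categorised ``input``.
    """
    if result_a.model is not model or result_b.model is not model:
        raise ModelError("propagation results come from a different model")
    categories: Dict[str, str] = {}
    for comp in model.components:
        name = comp.name
        in_a = name in result_a.frozen
        in_b = name in result_b.frozen
        if model.is_input(name) and not in_a and not in_b:
            categories[name] = "input"
        elif in_a and in_b:
            va, vb = result_a.frozen[name], result_b.frozen[name]
            if va != vb:
                categories[name] = "frozen_conflict"
            elif va == 0:
                categories[name] = "frozen_off_both"
            else:
                categories[name] = "frozen_on_both"
        elif in_a:
            categories[name] = (
                "frozen_off_A_only" if result_a.frozen[name] == 0 else "frozen_on_A_only"
            )
        elif in_b:
            categories[name] = (
                "frozen_off_B_only" if result_b.frozen[name] == 0 else "frozen_on_B_only"
            )
        else:
            categories[name] = "free_both"
    return DifferentialClassification(model, categories)


# ---------------------------------------------------------------------------
# Annotated graph export
# ---------------------------------------------------------------------------

def export_annotated_graph(
    model: LogicalModel,
    classification: DifferentialClassification,
    fmt: str = "dot",
) -> str:
    """Regulatory graph with nodes colored by differential category.

    One node per component carrying its category as a class attribute and
    the corresponding fill color; one edge per (regulator, target) pair.
    ``fmt`` is ``dot`` or ``graphml``.
    """
    if set(classification.categories) != set(model.names):
        raise ModelError("classification does not cover the model's components")
    edges = [
        (reg, comp.name)
        for comp in model.components
        for reg in sorted(model.functions[comp.name].regulators())
        if reg != comp.name or not model.is_input(comp.name)
    ]
    if fmt == "dot":
        lines = ["digraph regulatory_graph {", "  node [style=filled];"]
        for comp in model.components:
            cat = classification.categories[comp.name]
            color = CATEGORY_COLORS[cat]
            lines.append(
                f'  "{comp.name}" [fillcolor="{color}", category="{cat}"];'
            )
        for reg, target in edges:
            lines.append(f'  "{reg}" -> "{target}";')
        lines.append("}")
        return "\n".join(lines) + "\n"
    if fmt == "graphml":
        import networkx as nx

        graph = nx.DiGraph()
        for comp in model.components:
            cat = classification.categories[comp.name]
            graph.add_node(comp.name, category=cat, color=CATEGORY_COLORS[cat])
        graph.add_edges_from(edges)
        return "\n".join(nx.generate_graphml(graph)) + "\n"
    raise ModelError(f"unsupported graph format {fmt!r}")
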