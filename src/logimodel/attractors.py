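"""Stable states and minimal trap spaces, with brute-force oracles.

A stable state (fixed point) is a state where every component's rule
returns its current level.  A trap space (stable motif) is a subspace —
some components fixed at a level, the rest unrestricted — closed under the
dynamics: every successor of every state in the subspace stays inside, for
synchronous, asynchronous, or any other updating.  Minimal (most specific)
trap spaces approximate the attractors; their reachability is out of scope
here and must be assessed separately.

The production search routines reuse value propagation as a constraint
propagator; the ``*_exhaustive`` oracles enumerate states or subspaces
directly via the one-step successor relation and exist to validate the
search on small models.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, FrozenSet, List, Mapping, Optional, Set, Tuple

from .model_core import (
    Atom,
    Component,
    Const,
    Expr,
    LogicalFunction,
    LogicalModel,
    ModelError,
    Not,
    And,
    Or,
    PartialAssignment,
    State,
    identity_function,
    make_and,
    make_or,
)
from .propagation import Constant, Residual, propagate, simplify_under

__all__ = [
    "clamp_model",
    "stable_states",
    "stable_states_exhaustive",
    "TrapSpace",
    "minimal_trap_spaces",
    "minimal_trap_spaces_exhaustive",
    "is_trap_space",
    "booleanize",
    "debooleanize",
    "BooleanizationMapping",
]


def _constant_function(level: int) -> LogicalFunction:
    if level == 0:
        return LogicalFunction(((Const(0), 1),))
    return LogicalFunction(((Const(1), level),))


def clamp_model(model: LogicalModel, clamps: Optional[PartialAssignment]) -> LogicalModel:
    """Replace the rules of clamped components by constants (mutant model)."""
    if not clamps:
        return model
    model.check_assignment(clamps)
    functions = dict(model.functions)
    for name, level in clamps.items():
        functions[name] = _constant_function(level)
    components = tuple(
        Component(c.name, c.max_level, c.input and c.name not in clamps)
        for c in model.components
    )
    return LogicalModel(components, functions)


def _state_key(model: LogicalModel, state: Mapping[str, int]) -> Tuple[int, ...]:
    return tuple(state[name] for name in model.names)


# ---------------------------------------------------------------------------
# Stable states
# ---------------------------------------------------------------------------

def _is_stable(model: LogicalModel, state: Mapping[str, int]) -> bool:
    return all(
        model.functions[c.name].target(state) == state[c.name]
        for c in model.components
    )


def stable_states(
    model: LogicalModel, clamps: Optional[PartialAssignment] = None
) -> List[State]:
    """All fixed points of the (clamped) model, in lexicographic order.

    Depth-first search over component assignments, using value propagation
    as a constraint propagator: branches whose percolation forces a
    component to a value contradicting its own rule are pruned; complete
    leaves are verified exactly.
    """
    clamped = clamp_model(model, clamps)
    names = clamped.names
    results: List[State] = []

    def consistent(frozen: Dict[str, int]) -> bool:
        for name in frozen:
            outcome = simplify_under(clamped, clamped.functions[name], frozen)
            if isinstance(outcome, Constant) and outcome.level != frozen[name]:
                return False
        return True

    def search(branch: Dict[str, int]) -> None:
        frozen = propagate(clamped, branch).frozen
        if not consistent(frozen):
            return
        free = [n for n in names if n not in frozen]
        if not free:
            if _is_stable(clamped, frozen):
                results.append({n: frozen[n] for n in names})
            return
        pivot = free[0]
        for level in range(clamped.max_level(pivot) + 1):
            nxt = dict(branch)
            nxt[pivot] = level
            search(nxt)

    search({})
    results.sort(key=lambda s: _state_key(clamped, s))
    return results


def stable_states_exhaustive(
    model: LogicalModel, clamps: Optional[PartialAssignment] = None
) -> List[State]:
    """Brute-force fixed-point enumeration over all states (oracle)."""
    clamped = clamp_model(model, clamps)
    return [dict(s) for s in clamped.states() if _is_stable(clamped, s)]


# ---------------------------------------------------------------------------
# Trap spaces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrapSpace:
    """A subspace closed under the dynamics; free components unrestricted."""

    assignment: FrozenSet[Tuple[str, int]]

    @classmethod
    def of(cls, assignment: Mapping[str, int]) -> "TrapSpace":
        return cls(frozenset(assignment.items()))

    def as_dict(self) -> Dict[str, int]:
        return dict(self.assignment)

    def contains_subspace(self, other: "TrapSpace") -> bool:
        """True iff ``other``'s subspace is included in this one."""
        return self.assignment <= other.assignment

    def free_components(self, model: LogicalModel) -> List[str]:
        fixed = {name for name, _ in self.assignment}
        return [n for n in model.names if n not in fixed]


def is_trap_space(
    model: LogicalModel,
    sub: PartialAssignment,
    max_states: int = 1 << 20,
) -> bool:
    """Exhaustively check closure of a subspace under all updatings.

    True iff every synchronous and asynchronous successor of every state in
    the subspace stays in the subspace.  Intended as the small-model oracle;
    refuses subspaces larger than ``max_states``.
    """
    model.check_assignment(sub)
    free = [n for n in model.names if n not in sub]
    size = 1
    for name in free:
        size *= model.max_level(name) + 1
        if size > max_states:
            raise ModelError(
                f"subspace with {len(free)} free components exceeds the "
                f"exhaustive-check cap of {max_states} states"
            )
    ranges = [range(model.max_level(n) + 1) for n in free]
    for combo in product(*ranges):
        state = dict(sub)
        state.update(zip(free, combo))
        # One-step moves are +-1 toward the target, so it is enough to check
        # that every fixed component's target equals its fixed level.
        for name, level in sub.items():
            if model.functions[name].target(state) != level:
                return False
    return True


def _percolate_candidate(
    model: LogicalModel, partial: Dict[str, int]
) -> Optional[Dict[str, int]]:
    """Close a candidate fixing under forced constants.

    Returns None when some fixed component's rule is constant at a
    different level (no trap space refines this candidate).
    """
    fixed = dict(partial)
    changed = True
    while changed:
        changed = False
        for comp in model.components:
            name = comp.name
            outcome = simplify_under(model, model.functions[name], fixed)
            if isinstance(outcome, Constant):
                if name in fixed:
                    if outcome.level != fixed[name]:
                        return None
                else:
                    fixed[name] = outcome.level
                    changed = True
    return fixed


def minimal_trap_spaces(model: LogicalModel) -> List[TrapSpace]:
    """All minimal trap spaces, Boolean or multivalued.

    Branch-and-prune search over component/value fixings: candidates are
    closed under value percolation (a minimal trap space always is), fixings
    contradicted by a constant rule are pruned, and candidates whose fixed
    components are not yet all constant branch on the free regulators of an
    unresolved component.  Collected trap spaces are filtered for
    minimality.  Output is lexicographic (fixed level, or the max level + 1
    for free components, per declaration order).
    """
    found: Dict[FrozenSet[Tuple[str, int]], Dict[str, int]] = {}
    seen: Set[FrozenSet[Tuple[str, int]]] = set()

    def search(partial: Dict[str, int]) -> None:
        closed = _percolate_candidate(model, partial)
        if closed is None:
            return
        key = frozenset(closed.items())
        if key in seen:
            return
        seen.add(key)
        unresolved = [
            name
            for name in closed
            if isinstance(
                simplify_under(model, model.functions[name], closed), Residual
            )
        ]
        if unresolved:
            # Any trap space refining this candidate must fix at least one
            # currently-free regulator of an unresolved component.
            name = unresolved[0]
            outcome = simplify_under(model, model.functions[name], closed)
            assert isinstance(outcome, Residual)
            for reg in sorted(outcome.function.regulators()):
                if reg in closed:
                    continue
                for level in range(model.max_level(reg) + 1):
                    nxt = dict(closed)
                    nxt[reg] = level
                    search(nxt)
            return
        found[key] = closed
        # A smaller trap space may hide inside: branch on every free fixing.
        for comp in model.components:
            if comp.name in closed:
                continue
            for level in range(comp.max_level + 1):
                nxt = dict(closed)
                nxt[comp.name] = level
                search(nxt)

    search({})
    minimal = [
        assignment
        for key, assignment in found.items()
        if not any(other > key for other in found)
    ]
    return sorted(
        (TrapSpace.of(a) for a in minimal),
        key=lambda t: _subspace_key(model, t.as_dict()),
    )


def _subspace_key(model: LogicalModel, sub: Mapping[str, int]) -> Tuple[int, ...]:
    return tuple(
        sub.get(c.name, c.max_level + 1) for c in model.components
    )


def minimal_trap_spaces_exhaustive(model: LogicalModel) -> List[TrapSpace]:
    """Enumerate every subspace and keep the minimal closed ones (oracle).

    Uses precomputed one-step targets for every state, fully independent of
    the percolation-based search.  Exponential in both states and
    subspaces; for small models only.
    """
    names = model.names
    maxes = [model.max_level(n) for n in names]
    # target levels for every state, keyed by level tuple
    targets: Dict[Tuple[int, ...], Tuple[int, ...]] = {}
    for state in model.states():
        key = tuple(state[n] for n in names)
        targets[key] = tuple(model.functions[n].target(state) for n in names)

    traps: List[Dict[str, int]] = []
    options = [list(range(m + 1)) + [None] for m in maxes]  # None = free
    for choice in product(*options):
        free_idx = [i for i, v in enumerate(choice) if v is None]
        closed = True
        for combo in product(*(range(maxes[i] + 1) for i in free_idx)):
            key = list(choice)
            for i, v in zip(free_idx, combo):
                key[i] = v
            tgt = targets[tuple(key)]
            if any(
                choice[i] is not None and tgt[i] != choice[i]
                for i in range(len(names))
            ):
                closed = False
                break
        if closed:
            traps.append(
                {names[i]: v for i, v in enumerate(choice) if v is not None}
            )

    keys = [frozenset(t.items()) for t in traps]
    minimal = [
        traps[i]
        for i in range(len(traps))
        if not any(keys[j] > keys[i] for j in range(len(traps)))
    ]
    return sorted(
        (TrapSpace.of(t) for t in minimal),
        key=lambda t: _subspace_key(model, t.as_dict()),
    )


# ---------------------------------------------------------------------------
# Booleanization of multivalued models (threshold-indicator encoding)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BooleanizationMapping:
    """Maps each multivalued component to its threshold indicators.

    ``indicators[c] = [c_b1, ..., c_bl]`` where indicator ``k`` is active
    iff the level of ``c`` is at least ``k``.  Admissible Boolean states
    satisfy indicator monotonicity (``c_b(k+1)`` implies ``c_bk``).
    """

    indicators: Mapping[str, Tuple[str, ...]]

    def is_identity(self) -> bool:
        return not self.indicators

    def is_admissible(self, state: Mapping[str, int]) -> bool:
        for names in self.indicators.values():
            for lower, upper in zip(names, names[1:]):
                if state[upper] > state[lower]:
                    return False
        return True


def _translate(expr: Expr, indicator_of) -> Expr:
    if isinstance(expr, Const):
        return expr
    if isinstance(expr, Atom):
        return indicator_of(expr.component, expr.threshold)
    if isinstance(expr, Not):
        return Not(_translate(expr.child, indicator_of))
    if isinstance(expr, And):
        return make_and(*(_translate(c, indicator_of) for c in expr.children))
    if isinstance(expr, Or):
        return make_or(*(_translate(c, indicator_of) for c in expr.children))
    raise ModelError(f"unknown expression node {expr!r}")


def booleanize(model: LogicalModel) -> Tuple[LogicalModel, BooleanizationMapping]:
    """Encode a multivalued model as a Boolean one (van Ham indicators).

    Each component with max level l > 1 becomes l Boolean indicators for
    the thresholds 1..l.  Indicator updates preserve admissibility and the
    one-step-at-a-time level semantics, inadmissible states are never
    stable, and stable states of the encoding correspond bijectively to
    those of the multivalued model.  Boolean models are returned unchanged
    with an identity mapping.
    """
    if all(c.max_level == 1 for c in model.components):
        return model, BooleanizationMapping({})

    taken = set(model.names)
    indicators: Dict[str, Tuple[str, ...]] = {}
    for comp in model.components:
        if comp.max_level == 1:
            continue
        names = []
        for k in range(1, comp.max_level + 1):
            candidate = f"{comp.name}_b{k}"
            while candidate in taken:
                candidate += "_"
            taken.add(candidate)
            names.append(candidate)
        indicators[comp.name] = tuple(names)

    def indicator_of(name: str, threshold: int) -> Expr:
        if name in indicators:
            return Atom(indicators[name][threshold - 1])
        return Atom(name)

    components: List[Component] = []
    functions: Dict[str, LogicalFunction] = {}
    for comp in model.components:
        f = model.functions[comp.name]
        if comp.max_level == 1:
            components.append(comp)
            functions[comp.name] = LogicalFunction(
                ((_translate(f.cases[0][0], indicator_of), 1),)
            )
            continue
        names = indicators[comp.name]
        # at_least[k] := translated predicate "target of c >= k", honoring
        # first-match case semantics
        for k in range(1, comp.max_level + 1):
            terms: List[Expr] = []
            earlier: List[Expr] = []
            for condition, level in f.cases:
                translated = _translate(condition, indicator_of)
                if level >= k:
                    terms.append(
                        make_and(translated, *(Not(e) for e in earlier))
                        if earlier
                        else translated
                    )
                earlier.append(translated)
            at_least_k = make_or(*terms) if terms else Const(0)
            rise_guard = (
                make_and(at_least_k, Atom(names[k - 2])) if k > 1 else at_least_k
            )
            hold = Atom(names[k]) if k < comp.max_level else None
            rule = make_or(rise_guard, hold) if hold is not None else rise_guard
            components.append(Component(names[k - 1], 1, comp.input))
            functions[names[k - 1]] = LogicalFunction(((rule, 1),))
    encoded = LogicalModel(tuple(components), functions)
    return encoded, BooleanizationMapping(indicators)


def debooleanize(result, mapping: BooleanizationMapping):
    """Map Boolean-encoding results back to multivalued levels.

    Accepts a single (partial) assignment or a list/TrapSpace of them.  For
    each multivalued component, either all its indicators must be assigned
    (level = number of active indicators, admissibility required) or none
    (component free).  Inadmissible or partially-fixed indicator patterns
    raise ``ModelError``.
    """
    if isinstance(result, list):
        return [debooleanize(r, mapping) for r in result]
    if isinstance(result, TrapSpace):
        return TrapSpace.of(debooleanize(result.as_dict(), mapping))
    if not isinstance(result, Mapping):
        raise ModelError(f"cannot debooleanize {type(result).__name__}")
    if mapping.is_identity():
        return dict(result)
    indicator_owner = {
        ind: name for name, inds in mapping.indicators.items() for ind in inds
    }
    out: Dict[str, int] = {}
    for key, value in result.items():
        if key not in indicator_owner:
            out[key] = value
    for name, inds in mapping.indicators.items():
        assigned = [ind for ind in inds if ind in result]
        if not assigned:
            continue
        if len(assigned) != len(inds):
            raise ModelError(
                f"indicators of {name} are only partially assigned; the "
                f"subspace has no multivalued counterpart"
            )
        values = [result[ind] for ind in inds]
        if any(b > a for a, b in zip(values, values[1:])):
            raise ModelError(f"inadmissible indicator pattern for {name}: {values}")
        out[name] = sum(values)
    return out
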