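"""Core data model for Boolean and multivalued logical networks.

A logical model is a set of named components, each taking a discrete
activity level in ``0..max_level`` (``max_level = 1`` for Boolean
components), together with one update rule per component.  Rules are
expression trees over threshold atoms: the atom ``X:k`` is true in a state
iff the level of ``X`` is at least ``k`` (``X`` alone abbreviates ``X:1``).
Multivalued rules are ordered lists of ``(condition, target_level)`` cases;
the target of a state is the target level of the first case whose condition
holds, or 0 if none does.

Two serialisation dialects are supported:

* ``bnet`` — Boolean-only rule tables, one ``target, factors`` line per
  component, with operators ``!``, ``&``, ``|``, parentheses and the
  constants ``0``/``1``.  ``#`` starts a comment.  A component whose rule is
  exactly itself (``A, A``) is an input.
* ``native-json`` — a JSON document carrying ``max_level``, an explicit
  ``input`` flag and per-level condition cases, for multivalued models.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Set, Tuple

__all__ = [
    "Expr",
    "Const",
    "Atom",
    "Not",
    "And",
    "Or",
    "LogicalFunction",
    "Component",
    "LogicalModel",
    "ModelError",
    "ModelSyntaxError",
    "parse_model",
    "parse_expression",
    "write_model",
    "regulators",
    "evaluate_component",
    "successors",
    "validate_model",
    "identity_function",
    "make_and",
    "make_or",
]

State = Dict[str, int]
PartialAssignment = Dict[str, int]

NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")


class ModelError(ValueError):
    """Invalid model structure or invalid use of a model operation."""


class ModelSyntaxError(ModelError):
    """Parse error; carries the 1-based source line when known."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# Expressions
# ---------------------------------------------------------------------------

class Expr:
    """Base class for rule expressions."""

    __slots__ = ()

    def atoms(self) -> Iterator["Atom"]:
        raise NotImplementedError

    def evaluate(self, state: Mapping[str, int]) -> bool:
        raise NotImplementedError


@dataclass(frozen=True)
class Const(Expr):
    value: int  # 0 or 1

    def __post_init__(self):
        if self.value not in (0, 1):
            raise ModelError(f"constant must be 0 or 1, got {self.value}")

    def atoms(self):
        return iter(())

    def evaluate(self, state):
        return bool(self.value)

    def __str__(self):
        return str(self.value)


@dataclass(frozen=True)
class Atom(Expr):
    component: str
    threshold: int = 1

    def __post_init__(self):
        if self.threshold < 1:
            raise ModelError(f"atom threshold must be >= 1, got {self.threshold}")

    def atoms(self):
        yield self

    def evaluate(self, state):
        return state[self.component] >= self.threshold

    def __str__(self):
        if self.threshold == 1:
            return self.component
        return f"{self.component}:{self.threshold}"


@dataclass(frozen=True)
class Not(Expr):
    child: Expr

    def atoms(self):
        return self.child.atoms()

    def evaluate(self, state):
        return not self.child.evaluate(state)

    def __str__(self):
        c = self.child
        if isinstance(c, (Atom, Const, Not)):
            return f"!{c}"
        return f"!({c})"


@dataclass(frozen=True)
class And(Expr):
    children: Tuple[Expr, ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ModelError("AND requires at least 2 children")

    def atoms(self):
        for c in self.children:
            yield from c.atoms()

    def evaluate(self, state):
        return all(c.evaluate(state) for c in self.children)

    def __str__(self):
        parts = []
        for c in self.children:
            s = str(c)
            if isinstance(c, Or):
                s = f"({s})"
            parts.append(s)
        return " & ".join(parts)


@dataclass(frozen=True)
class Or(Expr):
    children: Tuple[Expr, ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ModelError("OR requires at least 2 children")

    def atoms(self):
        for c in self.children:
            yield from c.atoms()

    def evaluate(self, state):
        return any(c.evaluate(state) for c in self.children)

    def __str__(self):
        return " | ".join(str(c) for c in self.children)


# ---------------------------------------------------------------------------
# Expression parsing (recursive descent; ! > & > |)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_]*)(?::(?P<thr>\d+))?"
    r"|(?P<const>[01])"
    r"|(?P<op>[!&|()])"
    r"|(?P<bad>\S))"
)


def _tokenize(text: str, line: Optional[int]) -> List[Tuple[str, object]]:
    tokens: List[Tuple[str, object]] = []
    for m in _TOKEN_RE.finditer(text):
        if m.group("name"):
            thr = int(m.group("thr")) if m.group("thr") else 1
            if thr < 1:
                raise ModelSyntaxError(f"threshold must be >= 1 in '{m.group(0).strip()}'", line)
            tokens.append(("atom", (m.group("name"), thr)))
        elif m.group("const"):
            tokens.append(("const", int(m.group("const"))))
        elif m.group("op"):
            tokens.append((m.group("op"), None))
        else:
            raise ModelSyntaxError(f"unexpected character {m.group('bad')!r}", line)
    tokens.append(("end", None))
    return tokens


class _ExprParser:
    def __init__(self, tokens: List[Tuple[str, object]], line: Optional[int]):
        self.tokens = tokens
        self.pos = 0
        self.line = line

    def peek(self) -> str:
        return self.tokens[self.pos][0]

    def next(self) -> Tuple[str, object]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self) -> Expr:
        expr = self.parse_or()
        if self.peek() != "end":
            raise ModelSyntaxError(f"unexpected token after expression", self.line)
        return expr

    def parse_or(self) -> Expr:
        terms = [self.parse_and()]
        while self.peek() == "|":
            self.next()
            terms.append(self.parse_and())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_and(self) -> Expr:
        factors = [self.parse_unary()]
        while self.peek() == "&":
            self.next()
            factors.append(self.parse_unary())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def parse_unary(self) -> Expr:
        kind, value = self.next()
        if kind == "!":
            return Not(self.parse_unary())
        if kind == "(":
            expr = self.parse_or()
            if self.next()[0] != ")":
                raise ModelSyntaxError("missing closing parenthesis", self.line)
            return expr
        if kind == "atom":
            name, thr = value  # type: ignore[misc]
            return Atom(name, thr)
        if kind == "const":
            return Const(value)  # type: ignore[arg-type]
        raise ModelSyntaxError(f"expected expression, found {kind!r}", self.line)


def _make_nary(cls, absorbing: int, operands: Sequence[Expr]) -> Expr:
    children: List[Expr] = []
    for op in operands:
        if isinstance(op, Const):
            if op.value == absorbing:
                return Const(absorbing)
            continue
        if isinstance(op, cls):
            children.extend(op.children)
        else:
            children.append(op)
    if not children:
        return Const(1 - absorbing)
    if len(children) == 1:
        return children[0]
    return cls(tuple(children))


def make_and(*operands: Expr) -> Expr:
    """Conjunction with constant folding and same-operator flattening."""
    return _make_nary(And, 0, operands)


def make_or(*operands: Expr) -> Expr:
    """Disjunction with constant folding and same-operator flattening."""
    return _make_nary(Or, 1, operands)


def parse_expression(text: str, line: Optional[int] = None) -> Expr:
    """Parse a rule expression (``!`` > ``&`` > ``|``, parentheses allowed)."""
    text = text.strip()
    if not text:
        raise ModelSyntaxError("empty expression", line)
    return _ExprParser(_tokenize(text, line), line).parse()


# ---------------------------------------------------------------------------
# Components, functions, model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Component:
    name: str
    max_level: int = 1
    input: bool = False

    def __post_init__(self):
        if not NAME_RE.fullmatch(self.name):
            raise ModelError(f"invalid component name {self.name!r}")
        if self.max_level < 1:
            raise ModelError(f"max_level must be >= 1 for {self.name}")


@dataclass(frozen=True)
class LogicalFunction:
    """Ordered ``(condition, target_level)`` cases; implicit default target 0."""

    cases: Tuple[Tuple[Expr, int], ...]

    def __post_init__(self):
        for _, level in self.cases:
            if level < 1:
                raise ModelError("case target levels must be >= 1 (0 is the implicit default)")

    def target(self, state: Mapping[str, int]) -> int:
        for condition, level in self.cases:
            if condition.evaluate(state):
                return level
        return 0

    def atoms(self) -> Iterator[Atom]:
        for condition, _ in self.cases:
            yield from condition.atoms()

    def regulators(self) -> Set[str]:
        return {a.component for a in self.atoms()}


def identity_function(name: str, max_level: int = 1) -> LogicalFunction:
    """The self-copy rule marking an input: f(x) = x[name]."""
    cases = tuple((Atom(name, k), k) for k in range(max_level, 0, -1))
    return LogicalFunction(cases)


@dataclass(frozen=True)
class LogicalModel:
    """An immutable logical model ``M = (V, f)``.

    ``components`` keeps declaration order; ``functions`` maps each
    component name to its rule.  A component is an *input* when it carries
    the explicit flag or its rule is exactly the identity on itself.
    """

    components: Tuple[Component, ...]
    functions: Mapping[str, LogicalFunction]

    def __post_init__(self):
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise ModelError(f"duplicate component {dup!r}")
        declared = set(names)
        if set(self.functions) != declared:
            missing = declared - set(self.functions)
            extra = set(self.functions) - declared
            raise ModelError(
                f"functions do not cover components exactly "
                f"(missing={sorted(missing)}, undeclared={sorted(extra)})"
            )
        for comp in self.components:
            f = self.functions[comp.name]
            for _, level in f.cases:
                if level > comp.max_level:
                    raise ModelError(
                        f"{comp.name}: case target {level} exceeds max_level {comp.max_level}"
                    )
            if comp.max_level == 1:
                if len(f.cases) != 1 or f.cases[0][1] != 1:
                    raise ModelError(
                        f"{comp.name}: Boolean components need exactly one case with target 1"
                    )
        by_name = {c.name: c for c in self.components}
        for comp in self.components:
            for atom in self.functions[comp.name].atoms():
                if atom.component not in by_name:
                    raise ModelError(
                        f"{comp.name}: rule references undeclared component {atom.component!r}"
                    )
        object.__setattr__(self, "_by_name", by_name)

    # -- basic queries ------------------------------------------------------

    @property
    def names(self) -> List[str]:
        return [c.name for c in self.components]

    def component(self, name: str) -> Component:
        try:
            return self._by_name[name]  # type: ignore[attr-defined]
        except KeyError:
            raise ModelError(f"unknown component {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name  # type: ignore[attr-defined]

    def max_level(self, name: str) -> int:
        return self.component(name).max_level

    def is_input(self, name: str) -> bool:
        comp = self.component(name)
        if comp.input:
            return True
        return self.functions[name] == identity_function(name, comp.max_level)

    def inputs(self) -> List[str]:
        return [c.name for c in self.components if self.is_input(c.name)]

    def targets(self, name: str) -> List[str]:
        """Components whose rules mention ``name`` as a regulator."""
        self.component(name)
        return [c.name for c in self.components
                if name in self.functions[c.name].regulators()]

    def states(self) -> Iterator[State]:
        """All states of the model, in lexicographic declaration order."""
        ranges = [range(c.max_level + 1) for c in self.components]
        names = self.names
        for combo in product(*ranges):
            yield dict(zip(names, combo))

    def check_assignment(self, assignment: Mapping[str, int]) -> None:
        """Validate a (partial) assignment against declared bounds."""
        for name, level in assignment.items():
            comp = self.component(name)
            if not 0 <= level <= comp.max_level:
                raise ModelError(
                    f"level {level} out of range 0..{comp.max_level} for {name}"
                )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def regulators(model: LogicalModel, name: str) -> Set[str]:
    """Components appearing in the atoms of ``name``'s rule (R(c))."""
    model.component(name)
    return model.functions[name].regulators()


def evaluate_component(model: LogicalModel, state: Mapping[str, int], name: str) -> int:
    """Target level of ``name`` in ``state`` (first satisfied case, else 0)."""
    model.component(name)
    return model.functions[name].target(state)


def _step_toward(current: int, target: int) -> int:
    # Levels move by at most one per update.
    if target > current:
        return current + 1
    if target < current:
        return current - 1
    return current


def successors(model: LogicalModel, state: Mapping[str, int],
               mode: str = "asynchronous") -> List[State]:
    """One-step successors under synchronous or asynchronous updating.

    Synchronous: the single state where every component moves one step
    toward its target level.  Asynchronous: one successor per unstable
    component.  A stable state has itself as synchronous successor and an
    empty asynchronous successor list.
    """
    if mode not in ("synchronous", "asynchronous"):
        raise ModelError(f"unknown update mode {mode!r}")
    missing = [c.name for c in model.components if c.name not in state]
    if missing:
        raise ModelError(f"state is not total; missing {missing}")
    updates = {}
    for comp in model.components:
        nxt = _step_toward(state[comp.name], model.functions[comp.name].target(state))
        if nxt != state[comp.name]:
            updates[comp.name] = nxt
    if mode == "synchronous":
        succ = dict(state)
        succ.update(updates)
        return [succ]
    out = []
    for name, nxt in updates.items():
        succ = dict(state)
        succ[name] = nxt
        out.append(succ)
    return out


def _assignments_over(model: LogicalModel, names: Sequence[str]) -> Iterator[Dict[str, int]]:
    ranges = [range(model.max_level(n) + 1) for n in names]
    for combo in product(*ranges):
        yield dict(zip(names, combo))


def validate_model(model: LogicalModel, max_enumeration: int = 1 << 16) -> List[str]:
    """Structural diagnostics; an empty list means the model is clean.

    Reports thresholds above the regulator's max_level and cases whose
    condition is subsumed by an earlier case of the same rule (unreachable).
    The subsumption check enumerates the rule's regulator assignments, so it
    is complete for the bounded in-degrees typical of curated models.
    """
    diagnostics: List[str] = []
    for comp in model.components:
        f = model.functions[comp.name]
        for atom in f.atoms():
            reg_max = model.max_level(atom.component)
            if atom.threshold > reg_max:
                diagnostics.append(
                    f"{comp.name}: threshold {atom.component}:{atom.threshold} "
                    f"exceeds max_level {reg_max}"
                )
        regs = sorted(f.regulators())
        size = 1
        for r in regs:
            size *= model.max_level(r) + 1
        if size > max_enumeration:
            diagnostics.append(
                f"{comp.name}: rule over {len(regs)} regulators too large to "
                f"check for unreachable cases"
            )
            continue
        for i in range(1, len(f.cases)):
            cond_i = f.cases[i][0]
            reachable = False
            for assignment in _assignments_over(model, regs):
                if cond_i.evaluate(assignment) and not any(
                    f.cases[j][0].evaluate(assignment) for j in range(i)
                ):
                    reachable = True
                    break
            if not reachable:
                diagnostics.append(
                    f"{comp.name}: case {i + 1} ({cond_i} -> {f.cases[i][1]}) is unreachable"
                )
    return diagnostics


# ---------------------------------------------------------------------------
# Parsing / writing
# ---------------------------------------------------------------------------

def _parse_bnet(text: str) -> LogicalModel:
    entries: List[Tuple[str, Expr, int]] = []  # (name, expr, line)
    seen: Dict[str, int] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "," not in line:
            raise ModelSyntaxError("expected 'target, factors'", lineno)
        target, _, rhs = line.partition(",")
        target = target.strip()
        if not NAME_RE.fullmatch(target):
            raise ModelSyntaxError(f"invalid component name {target!r}", lineno)
        if target in seen:
            raise ModelSyntaxError(
                f"duplicate definition of {target} (first at line {seen[target]})", lineno
            )
        seen[target] = lineno
        entries.append((target, parse_expression(rhs, lineno), lineno))

    if not entries:
        raise ModelSyntaxError("no rules found")

    declared = {name for name, _, _ in entries}
    for name, expr, lineno in entries:
        for atom in expr.atoms():
            if atom.component not in declared:
                raise ModelSyntaxError(
                    f"rule for {name} references undeclared component {atom.component!r}",
                    lineno,
                )
            if atom.threshold != 1:
                raise ModelSyntaxError(
                    f"threshold atom {atom} not allowed in Boolean bnet dialect", lineno
                )

    components = tuple(
        Component(name, 1, input=(expr == Atom(name)))
        for name, expr, _ in entries
    )
    functions = {name: LogicalFunction(((expr, 1),)) for name, expr, _ in entries}
    return LogicalModel(components, functions)


def _parse_native_json(text: str) -> LogicalModel:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelSyntaxError(f"invalid JSON: {exc}", exc.lineno) from None
    if not isinstance(doc, dict) or "components" not in doc or "rules" not in doc:
        raise ModelSyntaxError("native-json requires 'components' and 'rules'")
    components = []
    for entry in doc["components"]:
        components.append(
            Component(
                entry["name"],
                int(entry.get("max_level", 1)),
                bool(entry.get("input", False)),
            )
        )
    functions: Dict[str, LogicalFunction] = {}
    comp_by_name = {c.name: c for c in components}
    for name, cases in doc["rules"].items():
        if name not in comp_by_name:
            raise ModelSyntaxError(f"rule for undeclared component {name!r}")
        parsed = tuple(
            (parse_expression(case["condition"]), int(case["target"]))
            for case in cases
        )
        functions[name] = LogicalFunction(parsed)
    for comp in components:
        if comp.name not in functions:
            if comp.input:
                functions[comp.name] = identity_function(comp.name, comp.max_level)
            else:
                raise ModelSyntaxError(f"missing rule for component {comp.name!r}")
    model = LogicalModel(tuple(components), functions)
    for comp in model.components:
        for atom in model.functions[comp.name].atoms():
            if atom.threshold > model.max_level(atom.component):
                raise ModelSyntaxError(
                    f"{comp.name}: threshold {atom} out of range for "
                    f"{atom.component} (max {model.max_level(atom.component)})"
                )
    return model


def parse_model(text: str, dialect: str = "bnet") -> LogicalModel:
    """Parse a model from ``bnet`` or ``native-json`` text."""
    if not text or not text.strip():
        raise ModelSyntaxError("empty model text")
    if dialect == "bnet":
        return _parse_bnet(text)
    if dialect == "native-json":
        return _parse_native_json(text)
    raise ModelError(f"unsupported dialect {dialect!r}")


def write_model(model: LogicalModel, dialect: str = "bnet") -> str:
    """Serialise a model; components keep declaration order.

    The bnet dialect is Boolean-only; requesting it for a multivalued model
    is an error.
    """
    if dialect == "bnet":
        for comp in model.components:
            if comp.max_level != 1:
                raise ModelError(
                    f"bnet dialect is Boolean-only; {comp.name} has "
                    f"max_level {comp.max_level} (use native-json)"
                )
        lines = []
        for comp in model.components:
            expr = model.functions[comp.name].cases[0][0]
            lines.append(f"{comp.name}, {expr}")
        return "\n".join(lines) + "\n"
    if dialect == "native-json":
        doc = {
            "components": [
                {"name": c.name, "max_level": c.max_level, "input": model.is_input(c.name)}
                for c in model.components
            ],
            "rules": {
                c.name: [
                    {"condition": str(cond), "target": level}
                    for cond, level in model.functions[c.name].cases
                ]
                for c in model.components
            },
        }
        return json.dumps(doc, indent=2) + "\n"
    raise ModelError(f"unsupported dialect {dialect!r}")
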