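"""Specification-based model verification.

A specification couples a *context* (input clamps and perturbations, all
expressed as clamps) with expected component activities, checked against an
oracle: the stable states of the clamped model, its minimal trap spaces, or
the frozen assignment of value propagation.  Specifications assemble into
suites (YAML is the canonical form) and run like unit tests, yielding
pass / fail / vacuous / error per case.

``vacuous`` is reported when the oracle produces no solutions at all: a
context without any attractor should alert the modeler rather than pass
silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import yaml

from .attractors import clamp_model, minimal_trap_spaces, stable_states
from .model_core import LogicalModel, ModelError, PartialAssignment
from .propagation import propagate
from .submodel import extract_submodel

__all__ = [
    "Constraint",
    "Specification",
    "TestSuite",
    "CaseResult",
    "Report",
    "load_suite",
    "run_case",
    "run_suite",
]

ORACLES = ("stable_states", "trap_spaces", "propagation")
QUANTIFIERS = ("all", "exists")


@dataclass(frozen=True)
class Constraint:
    """Expected activity: ``active`` (level >= 1), ``inactive`` (level 0),
    or an exact ``level=k``."""

    kind: str  # active | inactive | level
    level: Optional[int] = None

    @classmethod
    def parse(cls, text: str) -> "Constraint":
        text = str(text).strip()
        if text == "active":
            return cls("active")
        if text == "inactive":
            return cls("inactive")
        if text.startswith("level="):
            try:
                return cls("level", int(text[len("level="):]))
            except ValueError:
                pass
        raise ModelError(
            f"invalid constraint {text!r}; expected active, inactive or level=k"
        )

    def satisfied_by(self, level: int) -> bool:
        if self.kind == "active":
            return level >= 1
        if self.kind == "inactive":
            return level == 0
        return level == self.level

    def __str__(self):
        return self.kind if self.kind != "level" else f"level={self.level}"


@dataclass(frozen=True)
class Specification:
    """One verifiable test case for a model."""

    name: str
    context: Mapping[str, int] = field(default_factory=dict)
    expect: Mapping[str, Constraint] = field(default_factory=dict)
    oracle: str = "trap_spaces"
    quantifier: str = "all"
    select: Optional[Tuple[str, ...]] = None

    def __post_init__(self):
        if self.oracle not in ORACLES:
            raise ModelError(f"unknown oracle {self.oracle!r}")
        if self.quantifier not in QUANTIFIERS:
            raise ModelError(f"unknown quantifier {self.quantifier!r}")


@dataclass(frozen=True)
class TestSuite:
    __test__ = False  # not a pytest test class despite the domain name

    name: str
    model: Optional[str]  # reference (path) to the model document, if any
    cases: Tuple[Specification, ...]

    def __post_init__(self):
        if not self.cases:
            raise ModelError("a test suite must contain at least one case")
        names = [c.name for c in self.cases]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise ModelError(f"duplicate case name {dup!r}")


@dataclass(frozen=True)
class CaseResult:
    name: str
    status: str  # pass | fail | vacuous | error
    diagnostics: Tuple[str, ...] = ()


@dataclass(frozen=True)
class Report:
    suite: str
    cases: Tuple[CaseResult, ...]

    @property
    def totals(self) -> Dict[str, int]:
        out = {"pass": 0, "fail": 0, "vacuous": 0, "error": 0}
        for case in self.cases:
            out[case.status] += 1
        return out

    @property
    def ok(self) -> bool:
        totals = self.totals
        return totals["fail"] == 0 and totals["error"] == 0

    def to_dict(self) -> Dict:
        return {
            "suite": self.suite,
            "totals": self.totals,
            "cases": [
                {
                    "name": c.name,
                    "status": c.status,
                    "diagnostics": list(c.diagnostics),
                }
                for c in self.cases
            ],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent) + "\n"

    def summary(self) -> str:
        lines = [f"suite {self.suite}: " + ", ".join(
            f"{k}={v}" for k, v in self.totals.items()
        )]
        for case in self.cases:
            lines.append(f"  [{case.status.upper():7}] {case.name}")
            for diag in case.diagnostics:
                lines.append(f"            {diag}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# YAML loading
# ---------------------------------------------------------------------------

_SUITE_FIELDS = {"name", "model", "cases"}
_CASE_FIELDS = {"name", "select", "context", "oracle", "quantifier", "expect"}


def _reject_unknown(mapping: Mapping, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ModelError(f"{where}: unknown field(s) {sorted(unknown)}")


def load_suite(document: Union[str, Mapping]) -> TestSuite:
    """Load and validate a suite from YAML text (or a parsed mapping).

    Schema: ``suite: {name, model, cases: [{name, select?, context,
    oracle?, quantifier?, expect}]}``; unknown fields are rejected.
    """
    if isinstance(document, str):
        document = yaml.safe_load(document)
    if not isinstance(document, Mapping) or "suite" not in document:
        raise ModelError("suite document must have a top-level 'suite' mapping")
    _reject_unknown(document, {"suite"}, "document")
    suite_doc = document["suite"]
    if not isinstance(suite_doc, Mapping):
        raise ModelError("'suite' must be a mapping")
    _reject_unknown(suite_doc, _SUITE_FIELDS, "suite")
    cases_doc = suite_doc.get("cases")
    if not isinstance(cases_doc, list) or not cases_doc:
        raise ModelError("suite.cases must be a non-empty list")
    cases = []
    for i, case_doc in enumerate(cases_doc):
        where = f"suite.cases[{i}]"
        if not isinstance(case_doc, Mapping):
            raise ModelError(f"{where}: case must be a mapping")
        _reject_unknown(case_doc, _CASE_FIELDS, where)
        if "name" not in case_doc:
            raise ModelError(f"{where}: missing 'name'")
        select = case_doc.get("select")
        if isinstance(select, str):
            select = [s.strip() for s in select.split(",") if s.strip()]
        context = {
            str(k): int(v) for k, v in (case_doc.get("context") or {}).items()
        }
        expect = {
            str(k): Constraint.parse(v)
            for k, v in (case_doc.get("expect") or {}).items()
        }
        cases.append(
            Specification(
                name=str(case_doc["name"]),
                context=context,
                expect=expect,
                oracle=case_doc.get("oracle", "trap_spaces"),
                quantifier=case_doc.get("quantifier", "all"),
                select=tuple(select) if select else None,
            )
        )
    return TestSuite(
        name=str(suite_doc.get("name", "suite")),
        model=suite_doc.get("model"),
        cases=tuple(cases),
    )


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------

def _solutions(model: LogicalModel, spec: Specification) -> List[Mapping[str, int]]:
    """Oracle objects as (possibly partial) assignments."""
    context = dict(spec.context)
    if spec.oracle == "stable_states":
        return stable_states(model, context)
    if spec.oracle == "trap_spaces":
        return [t.as_dict() for t in minimal_trap_spaces(clamp_model(model, context))]
    return [propagate(model, context).frozen]


def _check_solution(
    solution: Mapping[str, int], expect: Mapping[str, Constraint]
) -> List[str]:
    """Violated constraints in one solution (empty list = satisfied)."""
    violations = []
    for name, constraint in expect.items():
        if name not in solution:
            violations.append(f"{name}: expected {constraint}, but unconstrained")
        elif not constraint.satisfied_by(solution[name]):
            violations.append(
                f"{name}: expected {constraint}, observed level {solution[name]}"
            )
    return violations


def run_case(model: LogicalModel, spec: Specification) -> CaseResult:
    """Evaluate one specification; exceptions become status ``error``."""
    try:
        target = model
        if spec.select:
            target = extract_submodel(model, spec.select)
        target.check_assignment(dict(spec.context))
        for name in spec.expect:
            target.component(name)
        solutions = _solutions(target, spec)
        if not solutions:
            return CaseResult(spec.name, "vacuous", ("oracle produced no solutions",))
        if spec.quantifier == "all":
            for idx, solution in enumerate(solutions):
                violations = _check_solution(solution, spec.expect)
                if violations:
                    return CaseResult(
                        spec.name,
                        "fail",
                        tuple(f"solution {idx + 1}: {v}" for v in violations),
                    )
            return CaseResult(spec.name, "pass")
        # exists
        witness_violations: Tuple[str, ...] = ()
        for idx, solution in enumerate(solutions):
            violations = _check_solution(solution, spec.expect)
            if not violations:
                return CaseResult(spec.name, "pass")
            if not witness_violations:
                witness_violations = tuple(
                    f"solution {idx + 1}: {v}" for v in violations
                )
        return CaseResult(
            spec.name,
            "fail",
            ("no solution satisfies all constraints; e.g. " + "; ".join(witness_violations),),
        )
    except Exception as exc:  # captured per-case; the suite keeps running
        return CaseResult(spec.name, "error", (f"{type(exc).__name__}: {exc}",))


def run_suite(model: LogicalModel, suite: TestSuite) -> Report:
    """Run every case independently; one case's error aborts nothing."""
    return Report(suite.name, tuple(run_case(model, spec) for spec in suite.cases))


def emit_pytest(suite: TestSuite, model_path: str, suite_path: str) -> str:
    """Render a suite as a native pytest module (YAML stays canonical).

    The generated module re-reads the model and suite documents and asserts
    each case passes, so suites integrate with any standard test runner.
    """
    lines = [
        '"""Generated from a logimodel specification suite; do not edit."""',
        "",
        "from pathlib import Path",
        "",
        "import pytest",
        "",
        "from logimodel.model_core import parse_model",
        "from logimodel.verification import load_suite, run_case",
        "",
        f"MODEL_PATH = {model_path!r}",
        f"SUITE_PATH = {suite_path!r}",
        "",
        "_dialect = 'native-json' if MODEL_PATH.endswith('.json') else 'bnet'",
        "_model = parse_model(Path(MODEL_PATH).read_text(), _dialect)",
        "_suite = load_suite(Path(SUITE_PATH).read_text())",
        "_cases = {case.name: case for case in _suite.cases}",
        "",
        "",
        "@pytest.mark.parametrize('name', sorted(_cases))",
        "def test_specification(name):",
        "    result = run_case(_model, _cases[name])",
        "    assert result.status == 'pass', result.diagnostics",
        "",
    ]
    return "\n".join(lines)
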