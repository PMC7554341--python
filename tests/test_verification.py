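"""Specification suites: loading, case execution, reporting."""

from pathlib import Path

import pytest

from logimodel.model_core import ModelError, parse_model
from logimodel.verification import (
    Constraint,
    Report,
    Specification,
    TestSuite,
    emit_pytest,
    load_suite,
    run_case,
    run_suite,
)

from conftest import random_models

EXAMPLES = Path(__file__).resolve().parent.parent / "examples"

GLOBAL_SUITE = """
suite:
  name: global
  model: tcell
  cases:
    - name: no_stimulation
      context: {TCR_stim: 0}
      oracle: stable_states
      expect: {Quiescence: active, Glycogenesis: active}
"""

QUIESCENT_MODEL = """\
TCR_stim, TCR_stim
Activation, TCR_stim
Quiescence, !Activation
Glycogenesis, Quiescence
"""


class TestLoading:
    def test_context_plus_expected_activities(self):
        suite = load_suite(GLOBAL_SUITE)
        case = suite.cases[0]
        assert case.context == {"TCR_stim": 0}
        assert case.expect["Quiescence"] == Constraint("active")
        assert case.oracle == "stable_states"
        assert case.quantifier == "all"

    def test_empty_suite_rejected(self):
        with pytest.raises(ModelError, match="non-empty"):
            load_suite("suite: {name: x, cases: []}")

    def test_duplicate_case_names_rejected(self):
        doc = """
        suite:
          name: x
          cases:
            - {name: a, expect: {}}
            - {name: a, expect: {}}
        """
        with pytest.raises(ModelError, match="duplicate"):
            load_suite(doc)

    def test_unknown_fields_rejected_with_path(self):
        doc = "suite:\n  name: x\n  cases:\n    - {name: a, oracel: typo}\n"
        with pytest.raises(ModelError, match=r"cases\[0\].*oracel"):
            load_suite(doc)

    def test_invalid_constraint_rejected(self):
        doc = "suite:\n  name: x\n  cases:\n    - {name: a, expect: {X: maybe}}\n"
        with pytest.raises(ModelError, match="constraint"):
            load_suite(doc)

    def test_level_constraint(self):
        assert Constraint.parse("level=2").satisfied_by(2)
        assert not Constraint.parse("level=2").satisfied_by(1)

    def test_global_specification_runs_against_model(self):
        suite = load_suite(GLOBAL_SUITE)
        report = run_suite(parse_model(QUIESCENT_MODEL), suite)
        assert report.totals["pass"] == 1

    def test_shipped_calcium_suite_loads(self):
        suite = load_suite((EXAMPLES / "calcium_suite.yaml").read_text())
        assert len(suite.cases) == 2


class TestRunCase:
    def test_all_stable_states_satisfy(self):
        m = parse_model("A, !S\nS, S")
        spec = Specification(
            "quiescent",
            context={"S": 0},
            oracle="stable_states",
            expect={"A": Constraint("active")},
        )
        assert run_case(m, spec).status == "pass"

    def test_calcium_regression_pair(self, calcium_default, calcium_corrected):
        spec = Specification(
            "rest_ER_full_without_pump",
            context={"IP3R_stim": 0},
            oracle="stable_states",
            quantifier="exists",
            expect={
                "Calcium_ER": Constraint("active"),
                "SERCA": Constraint("inactive"),
            },
        )
        assert run_case(calcium_default, spec).status == "fail"
        assert run_case(calcium_corrected, spec).status == "pass"

    def test_no_stable_state_is_vacuous_not_pass(self):
        m = parse_model("A, !A")
        spec = Specification(
            "impossible", oracle="stable_states", expect={"A": Constraint("active")}
        )
        assert run_case(m, spec).status == "vacuous"

    def test_select_extracts_submodel_first(self):
        m = parse_model("Z, Z\nA, Z\nB, A")
        # within the sub-model around B, A is an explorable input, so a
        # stable state with B active exists regardless of Z's cascade
        spec = Specification(
            "local",
            select=("B",),
            oracle="stable_states",
            quantifier="exists",
            expect={"B": Constraint("active")},
        )
        assert run_case(m, spec).status == "pass"

    def test_propagation_oracle_free_component_is_unconstrained(self, figure3):
        spec = Specification(
            "perc",
            context={"C": 1},
            oracle="propagation",
            expect={"E": Constraint("active")},
        )
        result = run_case(figure3, spec)
        assert result.status == "fail"
        assert any("unconstrained" in d for d in result.diagnostics)

    def test_propagation_oracle_checks_frozen_values(self, figure3):
        spec = Specification(
            "perc",
            context={"C": 1},
            oracle="propagation",
            expect={"D": Constraint("active")},
        )
        assert run_case(figure3, spec).status == "pass"

    def test_trap_space_oracle_covers_cyclic_behaviour(self):
        # A oscillates, so no stable state exists, but the (single) minimal
        # trap space still constrains B
        m = parse_model("A, !A\nB, 1")
        spec = Specification("cyc", expect={"B": Constraint("active")})
        assert spec.oracle == "trap_spaces"
        assert run_case(m, spec).status == "pass"

    def test_unknown_component_is_error(self, figure3):
        spec = Specification("bad", expect={"nope": Constraint("active")})
        result = run_case(figure3, spec)
        assert result.status == "error"
        assert "nope" in result.diagnostics[0]

    def test_fail_diagnostics_name_a_witness(self, figure3):
        spec = Specification(
            "all_on",
            oracle="stable_states",
            expect={"D": Constraint("active")},
        )
        result = run_case(figure3, spec)
        assert result.status == "fail"
        assert "D" in result.diagnostics[0]


class TestRunSuite:
    def test_shipped_suite_passes_on_corrected_model(self, calcium_corrected):
        suite = load_suite((EXAMPLES / "calcium_suite.yaml").read_text())
        report = run_suite(calcium_corrected, suite)
        assert report.totals == {"pass": 2, "fail": 0, "vacuous": 0, "error": 0}

    def test_shipped_suite_catches_default_rule(self, calcium_default):
        suite = load_suite((EXAMPLES / "calcium_suite.yaml").read_text())
        report = run_suite(calcium_default, suite)
        assert report.totals["fail"] == 1
        assert not report.ok

    def test_one_error_does_not_abort_the_suite(self, figure3):
        suite = TestSuite(
            "mixed",
            None,
            (
                Specification("bad", expect={"nope": Constraint("active")}),
                Specification(
                    "good",
                    context={"C": 1},
                    oracle="propagation",
                    expect={"D": Constraint("active")},
                ),
            ),
        )
        report = run_suite(figure3, suite)
        assert [c.status for c in report.cases] == ["error", "pass"]

    def test_totals_invariant_under_reordering(self, calcium_corrected):
        suite = load_suite((EXAMPLES / "calcium_suite.yaml").read_text())
        reordered = TestSuite(suite.name, suite.model, tuple(reversed(suite.cases)))
        assert (
            run_suite(calcium_corrected, suite).totals
            == run_suite(calcium_corrected, reordered).totals
        )

    def test_empty_expectation_never_fails(self):
        for m in random_models(15, range(2, 7), seed_base=21_000):
            for oracle in ("stable_states", "trap_spaces", "propagation"):
                result = run_case(m, Specification("noop", oracle=oracle))
                assert result.status in ("pass", "vacuous")

    def test_constraints_passing_all_trap_spaces_pass_all_stable_states(self):
        # stable states are minimal trap spaces with nothing left free
        from logimodel.attractors import minimal_trap_spaces, stable_states

        for m in random_models(15, range(2, 8), seed_base=22_000):
            traps = [t.as_dict() for t in minimal_trap_spaces(m)]
            for state in stable_states(m):
                assert any(
                    all(state[k] == v for k, v in t.items()) and
                    all(k in state for k in t)
                    for t in traps
                )

    def test_report_json_is_machine_readable(self, calcium_corrected):
        import json

        suite = load_suite((EXAMPLES / "calcium_suite.yaml").read_text())
        report = run_suite(calcium_corrected, suite)
        doc = json.loads(report.to_json())
        assert doc["totals"]["pass"] == 2
        assert {c["name"] for c in doc["cases"]} == {c.name for c in suite.cases}


class TestEmission:
    def test_emitted_module_passes_under_pytest(self, tmp_path, calcium_corrected):
        from logimodel.model_core import write_model

        model_path = tmp_path / "model.bnet"
        model_path.write_text(write_model(calcium_corrected))
        suite_path = tmp_path / "suite.yaml"
        suite_path.write_text((EXAMPLES / "calcium_suite.yaml").read_text())
        suite = load_suite(suite_path.read_text())
        module = emit_pytest(suite, str(model_path), str(suite_path))
        test_file = tmp_path / "test_generated.py"
        test_file.write_text(module)

        import subprocess
        import sys

        proc = subprocess.run(
            [sys.executable, "-m", "pytest", "-q", "-o", "addopts=",
             "-p", "no:cacheprovider", str(test_file)],
            capture_output=True,
            text=True,
        )
        assert proc.returncode == 0, proc.stdout + proc.stderr
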