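"""Value percolation, differential comparison, and graph export."""

import random
from itertools import product

import pytest

from logimodel.model_core import Atom, LogicalFunction, ModelError, Not, parse_model
from logimodel.propagation import (
    Constant,
    Residual,
    compare_propagations,
    export_annotated_graph,
    propagate,
    simplify_under,
    tally,
)
from logimodel.attractors import clamp_model, is_trap_space, stable_states_exhaustive

from conftest import random_models


def simplify_rule(model, name, assignment):
    return simplify_under(model, model.functions[name], assignment)


def boolean_equivalent(fn_a, fn_b, regulators):
    """Truth-table equivalence of two Boolean single-case rules."""
    for combo in product((0, 1), repeat=len(regulators)):
        state = dict(zip(regulators, combo))
        if fn_a.target(state) != fn_b.target(state):
            return False
    return True


class TestSimplifyUnder:
    def test_activator_present_makes_rule_constant(self, figure3):
        assert simplify_rule(figure3, "D", {"C": 1}) == Constant(1)

    def test_partial_substitution_leaves_residual(self, figure3):
        outcome = simplify_rule(figure3, "E", {"D": 1})
        assert isinstance(outcome, Residual)
        assert outcome.function.cases == ((Not(Atom("F")), 1),)

    def test_annihilating_inhibitor(self):
        m = parse_model("X, A & !B\nA, A\nB, B")
        assert simplify_rule(m, "X", {"B": 1}) == Constant(0)

    def test_constancy_detected_semantically_not_syntactically(self):
        # A | !A is constant 1 although no regulator is assigned
        m = parse_model("X, A | !A\nA, A")
        assert simplify_rule(m, "X", {}) == Constant(1)

    def test_unknown_component_in_assignment(self, figure3):
        with pytest.raises(ModelError, match="unknown"):
            simplify_rule(figure3, "D", {"Z": 1})


class TestPropagate:
    def test_input_activation_freezes_downstream_core(self, figure3):
        result = propagate(figure3, {"C": 1})
        assert result.frozen == {"C": 1, "D": 1}
        assert result.free_inputs == ["A", "B", "F"]
        assert set(result.residuals) == {"E"}
        assert result.residuals["E"].cases == ((Not(Atom("F")), 1),)

    def test_constant_source_percolates_without_clamps(self):
        m = parse_model("A, 1\nB, A")
        assert propagate(m, {}).frozen == {"A": 1, "B": 1}

    def test_mutual_inhibition_resolves_under_clamp(self):
        m = parse_model("A, !B\nB, !A")
        assert propagate(m, {"A": 1}).frozen == {"A": 1, "B": 0}

    def test_clamp_overrides_rule(self):
        # B's rule would force it ON, but the knockout clamp wins
        m = parse_model("A, 1\nB, A")
        assert propagate(m, {"B": 0}).frozen == {"A": 1, "B": 0}

    def test_out_of_range_clamp_rejected(self, figure3):
        with pytest.raises(ModelError, match="out of range"):
            propagate(figure3, {"C": 2})

    def test_idempotence_on_frozen_result(self):
        for m in random_models(25, range(3, 10), seed_base=5000):
            rng = random.Random(42)
            names = m.names
            clamps = {
                n: rng.randint(0, m.max_level(n))
                for n in rng.sample(names, rng.randint(0, min(3, len(names))))
            }
            first = propagate(m, clamps)
            again = propagate(m, dict(first.frozen))
            assert again.frozen == first.frozen
            assert again.residuals == first.residuals

    def test_confluence_under_worklist_permutations(self):
        for i, m in enumerate(random_models(20, range(4, 10), seed_base=6000)):
            rng = random.Random(i)
            clamps = {n: rng.randint(0, 1) for n in rng.sample(m.names, 2)}
            reference = propagate(m, clamps)
            for k in range(10):
                shuffled = propagate(m, clamps, rng=random.Random(k))
                assert shuffled.frozen == reference.frozen
                assert shuffled.residuals == reference.residuals

    def test_frozen_assignment_is_trap_space_of_clamped_model(self):
        rng = random.Random(11)
        for m in random_models(40, range(3, 11), seed_base=7000):
            clamps = {
                n: rng.randint(0, m.max_level(n))
                for n in rng.sample(m.names, rng.randint(0, 3))
            }
            frozen = propagate(m, clamps).frozen
            assert is_trap_space(clamp_model(m, clamps), frozen)

    def test_stable_states_agree_with_frozen_components(self):
        rng = random.Random(13)
        for m in random_models(30, range(3, 11), seed_base=8000):
            clamps = {n: rng.randint(0, 1) for n in rng.sample(m.names, 2)}
            frozen = propagate(m, clamps).frozen
            for state in stable_states_exhaustive(m, clamps):
                assert all(state[n] == v for n, v in frozen.items())

    def test_reduction_conserves_stable_states(self):
        # stable states of the residual model over free components, extended
        # by the frozen values, are exactly those of the clamped model
        rng = random.Random(17)
        for m in random_models(25, range(3, 11), seed_base=9000):
            clamps = {n: rng.randint(0, 1) for n in rng.sample(m.names, 2)}
            result = propagate(m, clamps)
            full = stable_states_exhaustive(m, clamps)

            free = [n for n in m.names if n not in result.frozen]
            reduced = []
            for combo in product(*(range(m.max_level(n) + 1) for n in free)):
                state = dict(result.frozen)
                state.update(zip(free, combo))
                stable = True
                for n in free:
                    fn = result.residuals.get(n) or m.functions[n]
                    if fn.target(state) != state[n]:
                        stable = False
                        break
                if stable:
                    reduced.append(state)

            key = lambda s: tuple(s[n] for n in m.names)
            assert sorted(reduced, key=key) == sorted(full, key=key)


class TestTally:
    def test_six_node_example(self, figure3):
        counts = tally(figure3, propagate(figure3, {"C": 1}))
        assert counts == {"frozen_inactive": 0, "frozen_active": 1, "free": 1}

    def test_no_constant_rules_all_free(self):
        m = parse_model("A, A\nX, A & !Y\nY, X")
        counts = tally(m, propagate(m, {}))
        assert counts == {"frozen_inactive": 0, "frozen_active": 0, "free": 2}

    def test_constant_sources_counted_frozen(self):
        m = parse_model("A, 0\nB, A")
        counts = tally(m, propagate(m, {}))
        assert counts == {"frozen_inactive": 2, "frozen_active": 0, "free": 0}

    def test_clamped_non_input_counts_as_frozen(self):
        m = parse_model("A, A\nX, A\nY, X")
        counts = tally(m, propagate(m, {"X": 1}))
        assert counts["frozen_active"] == 2  # X itself and Y downstream


class TestCompare:
    def test_same_freeze_lands_in_both_category(self, figure3):
        res_a = propagate(figure3, {"A": 0, "B": 0, "C": 0})
        res_b = propagate(figure3, {"C": 0, "A": 0, "B": 0})
        cls = compare_propagations(figure3, res_a, res_b)
        assert cls.categories["D"] == "frozen_off_both"
        assert cls.table()["frozen_inactive"]["intersection"] >= 1

    def test_one_sided_freeze(self, figure3):
        res_a = propagate(figure3, {"C": 1})
        res_b = propagate(figure3, {})
        cls = compare_propagations(figure3, res_a, res_b)
        assert cls.categories["D"] == "frozen_on_A_only"
        assert cls.categories["E"] == "free_both"

    def test_identical_results_have_no_only_categories(self, figure3):
        res = propagate(figure3, {"C": 1})
        cls = compare_propagations(figure3, res, res)
        assert all("only" not in cat for cat in cls.categories.values())

    def test_ab_columns_sum_to_non_input_count(self):
        rng = random.Random(23)
        for m in random_models(20, range(4, 9), seed_base=10_000):
            ca = {n: rng.randint(0, 1) for n in rng.sample(m.names, 2)}
            cb = {n: rng.randint(0, 1) for n in rng.sample(m.names, 2)}
            cls = compare_propagations(m, propagate(m, ca), propagate(m, cb))
            rows = cls.table()
            n_counted = sum(1 for c in m.components if not m.is_input(c.name))
            assert sum(rows[r]["A"] for r in rows) == n_counted
            assert sum(rows[r]["B"] for r in rows) == n_counted

    def test_categories_partition_components(self, figure3):
        cls = compare_propagations(
            figure3, propagate(figure3, {"C": 1}), propagate(figure3, {"F": 1})
        )
        assert set(cls.categories) == set(figure3.names)


class TestExport:
    def test_dot_has_all_nodes_and_matching_categories(self, figure3):
        cls = compare_propagations(
            figure3, propagate(figure3, {"C": 1}), propagate(figure3, {"F": 1})
        )
        dot = export_annotated_graph(figure3, cls, "dot")
        for name in figure3.names:
            assert f'"{name}" [' in dot
            assert f'category="{cls.categories[name]}"' in dot
        assert '"D" -> "E";' in dot

    def test_all_free_classification(self):
        m = parse_model("A, A\nX, A & !Y\nY, X")
        cls = compare_propagations(m, propagate(m, {}), propagate(m, {}))
        dot = export_annotated_graph(m, cls, "dot")
        assert 'category="free_both"' in dot
        assert cls.categories["A"] == "input"

    def test_graphml_roundtrips_through_networkx(self, figure3):
        import networkx as nx

        cls = compare_propagations(
            figure3, propagate(figure3, {"C": 1}), propagate(figure3, {"F": 1})
        )
        text = export_annotated_graph(figure3, cls, "graphml")
        graph = nx.parse_graphml(text)
        assert set(graph.nodes) == set(figure3.names)
        assert graph.nodes["D"]["category"] == cls.categories["D"]
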