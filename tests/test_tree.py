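"""Decision-tree validation, rollback and the path-enumeration oracle."""

import dataclasses

import numpy as np
import pytest

from treecea import (
    Branch,
    ChanceNode,
    Complement,
    CostTerm,
    DecisionTree,
    ParameterSet,
    ParameterSpec,
    Ref,
    Strategy,
    TerminalNode,
    TreeValidationError,
    enumerate_paths,
    rollback,
    validate_tree,
)
from conftest import random_tree, two_branch_tree


def single_terminal_tree():
    params = ParameterSet(
        [ParameterSpec("c", "cost", 100.0), ParameterSpec("u", "utility", 0.5)]
    )
    tree = DecisionTree(
        strategies=[Strategy("only", "t")],
        nodes={"t": TerminalNode("t", (CostTerm("c"),), "u")},
    )
    return tree, params


class TestValidate:
    def test_complement_forces_unit_sum(self):
        tree, params = two_branch_tree()
        assert validate_tree(tree, params) == []

    def test_explicit_probabilities_not_summing_to_one(self):
        params = ParameterSet(
            [
                ParameterSpec("p1", "probability", 0.6),
                ParameterSpec("p2", "probability", 0.5),
                ParameterSpec("c", "cost", 1.0),
                ParameterSpec("u", "utility", 0.5),
            ]
        )
        tree = DecisionTree(
            strategies=[Strategy("S", "root")],
            nodes={
                "root": ChanceNode("root", (Branch("a", Ref("p1")), Branch("b", Ref("p2")))),
                "a": TerminalNode("a", (CostTerm("c"),), "u"),
                "b": TerminalNode("b", (CostTerm("c"),), "u"),
            },
        )
        violations = validate_tree(tree, params)
        assert len(violations) == 1
        v = violations[0]
        assert v.code == "probability-sum" and v.where == "root"
        assert "1.1" in v.message

    def test_unresolved_parameter_is_named(self):
        tree, params = two_branch_tree()
        bad = DecisionTree(
            strategies=tree.strategies,
            nodes={**tree.nodes, "hi": TerminalNode("hi", (CostTerm("nope"),), "u_hi")},
        )
        violations = validate_tree(bad, params)
        assert any(v.code == "unresolved-parameter" and "nope" in v.message for v in violations)

    def test_probability_outside_unit_interval(self):
        tree, params = two_branch_tree()
        shifted = ParameterSet(
            [
                ParameterSpec("p", "probability", 0.25),
                ParameterSpec("c_hi", "cost", 1000.0),
                ParameterSpec("c_lo", "cost", 200.0),
                ParameterSpec("u_hi", "utility", 0.6),
                ParameterSpec("u_lo", "utility", 0.8),
            ]
        )
        # bypass spec-level clamping by feeding values straight to rollback
        with pytest.raises(TreeValidationError):
            rollback(tree, {**shifted.base_values(), "p": 1.5})

    def test_two_complements_rejected(self):
        params = ParameterSet(
            [ParameterSpec("c", "cost", 1.0), ParameterSpec("u", "utility", 0.5)]
        )
        tree = DecisionTree(
            strategies=[Strategy("S", "root")],
            nodes={
                "root": ChanceNode(
                    "root", (Branch("a", Complement()), Branch("b", Complement()))
                ),
                "a": TerminalNode("a", (CostTerm("c"),), "u"),
                "b": TerminalNode("b", (CostTerm("c"),), "u"),
            },
        )
        assert any(v.code == "multiple-complements" for v in validate_tree(tree, params))

    def test_bundled_fixture_is_valid(self, picc_model):
        assert validate_tree(picc_model.tree, picc_model.params) == []


class TestRollback:
    def test_degenerate_single_terminal(self):
        tree, params = single_terminal_tree()
        (o,) = rollback(tree, params.base_values())
        assert (o.expected_cost, o.expected_effect) == (100.0, 0.5)

    def test_two_branch_hand_arithmetic(self, simple_tree):
        tree, params = simple_tree
        (o,) = rollback(tree, params.base_values())
        assert o.expected_cost == pytest.approx(400.0, abs=1e-12)
        assert o.expected_effect == pytest.approx(0.75, abs=1e-12)

    def test_refuses_invalid_values(self, simple_tree):
        tree, params = simple_tree
        values = params.base_values()
        values["p"] = -0.2
        with pytest.raises(TreeValidationError):
            rollback(tree, values)


class TestEnumeratePaths:
    def test_two_branch_paths(self, simple_tree):
        tree, params = simple_tree
        paths = enumerate_paths(tree, params.base_values())
        assert sorted(p.probability for p in paths) == [0.25, 0.75]

    def test_single_terminal_single_path(self):
        tree, params = single_terminal_tree()
        (p,) = enumerate_paths(tree, params.base_values())
        assert p.probability == 1.0 and p.cost == 100.0

    def test_fixture_paths_aggregate_to_rollback(self, picc_model, base_outcomes):
        values = picc_model.params.base_values()
        paths = enumerate_paths(picc_model.tree, values)
        for outcome in base_outcomes:
            mine = [p for p in paths if p.strategy == outcome.strategy]
            assert sum(p.probability for p in mine) == pytest.approx(1.0, abs=1e-9)
            assert sum(p.probability * p.cost for p in mine) == pytest.approx(
                outcome.expected_cost, abs=1e-9 * max(1.0, outcome.expected_cost)
            )
            assert sum(p.probability * p.effect for p in mine) == pytest.approx(
                outcome.expected_effect, abs=1e-9
            )


class TestProperties:
    @pytest.mark.parametrize("seed", range(40))
    def test_rollback_equals_path_aggregation_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(5):
            tree, params = random_tree(rng)
            values = params.base_values()
            (o,) = rollback(tree, values)
            paths = enumerate_paths(tree, values)
            assert sum(p.probability for p in paths) == pytest.approx(1.0, abs=1e-9)
            assert sum(p.probability * p.cost for p in paths) == pytest.approx(
                o.expected_cost, rel=1e-9, abs=1e-9
            )
            assert sum(p.probability * p.effect for p in paths) == pytest.approx(
                o.expected_effect, rel=1e-9, abs=1e-9
            )

    def test_cost_linearity_effects_unchanged(self):
        rng = np.random.default_rng(11)
        tree, params = random_tree(rng)
        values = params.base_values()
        (o1,) = rollback(tree, values)
        k = 3.5
        scaled = {
            name: v * k if name.startswith("c_") else v for name, v in values.items()
        }
        (o2,) = rollback(tree, scaled)
        assert o2.expected_cost == pytest.approx(k * o1.expected_cost, rel=1e-12)
        assert o2.expected_effect == o1.expected_effect

    def test_merging_identical_sibling_branches_preserves_rollback(self):
        # p1 -> T, p2 -> T', complement -> U with T == T' payoff-wise
        params = ParameterSet(
            [
                ParameterSpec("p1", "probability", 0.2),
                ParameterSpec("p2", "probability", 0.3),
                ParameterSpec("p12", "probability", 0.5),
                ParameterSpec("c_t", "cost", 700.0),
                ParameterSpec("c_u", "cost", 100.0),
                ParameterSpec("u_t", "utility", 0.4),
                ParameterSpec("u_u", "utility", 0.9),
            ]
        )
        t = TerminalNode("t", (CostTerm("c_t"),), "u_t")
        t2 = dataclasses.replace(t, id="t2")
        u = TerminalNode("u", (CostTerm("c_u"),), "u_u")
        split = DecisionTree(
            strategies=[Strategy("S", "root")],
            nodes={
                "root": ChanceNode(
                    "root",
                    (Branch("t", Ref("p1")), Branch("t2", Ref("p2")), Branch("u", Complement())),
                ),
                "t": t,
                "t2": t2,
                "u": u,
            },
        )
        merged = DecisionTree(
            strategies=[Strategy("S", "root")],
            nodes={
                "root": ChanceNode(
                    "root", (Branch("t", Ref("p12")), Branch("u", Complement()))
                ),
                "t": t,
                "u": u,
            },
        )
        values = params.base_values()
        (a,) = rollback(split, values)
        (b,) = rollback(merged, values)
        assert a.expected_cost == pytest.approx(b.expected_cost, abs=1e-12)
        assert a.expected_effect == pytest.approx(b.expected_effect, abs=1e-12)
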