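"""Structural model: validation, editing operations and their invariants."""

import numpy as np
import pytest

from grncontrol import (
    Connection,
    NetworkValidationError,
    NodeSpec,
    TruthTable,
    add_input_loops,
    build_network,
    delete_connection,
    delete_outgoing,
    split_connection_input,
    split_node_outputs,
)
from grncontrol.network import structural_hash
from grncontrol.dynamics import CompiledNetwork


class TestValidation:
    def test_mutual_inhibition_builds(self, toggle):
        assert set(toggle.node_names) == {"A", "B"}
        assert all(not c.activating for c in toggle.connections)

    def test_edgeless_network_is_valid(self):
        net = build_network(["X", "Y", "Z"], [], interpolation="boolecube")
        assert net.density == 0.0
        assert all(net.is_input(n) for n in net.node_names)

    def test_dangling_endpoint_rejected(self):
        with pytest.raises(NetworkValidationError, match="Z"):
            build_network(["A", "B"], [("A", "Z", "+")])

    def test_duplicate_edge_rejected(self):
        with pytest.raises(NetworkValidationError, match="duplicate"):
            build_network(["A", "B"], [("A", "B", "+"), ("A", "B", "-")])

    def test_duplicate_node_rejected(self):
        with pytest.raises(NetworkValidationError, match="duplicate node"):
            build_network(["A", "A"], [])

    def test_rule_arity_must_match_incoming(self):
        rule = TruthTable(("A", "B"), (0, 0, 0, 1))
        with pytest.raises(NetworkValidationError, match="rule inputs"):
            build_network(
                [NodeSpec("A"), NodeSpec("C", rule=rule)],
                [("A", "C", "+")],
                interpolation="boolecube",
            )

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(NetworkValidationError, match="weight"):
            Connection("A", "B", "+", 0.0)

    def test_density_of_toy_network(self, toy):
        assert toy.density == pytest.approx(7 / 6)


class TestDeletion:
    def test_deleting_only_input_orphans_node(self, toy):
        smaller = delete_connection(toy, "B", "E")
        assert smaller.is_input("E")
        assert len(smaller.connections) == len(toy.connections) - 1

    def test_missing_connection_raises(self, toy):
        with pytest.raises(NetworkValidationError):
            delete_connection(toy, "F", "A")

    def test_delete_readd_restores_derivative_field(self, toy, rng):
        removed = toy.connection("C", "D")
        rebuilt = build_network(
            toy.nodes,
            delete_connection(toy, "C", "D").connections + (removed,),
            toy.interpolation,
        )
        c0, c1 = CompiledNetwork(toy), CompiledNetwork(rebuilt)
        states = rng.uniform(size=(100, len(toy.nodes)))
        assert np.allclose(c0.derivative(states), c1.derivative(states))

    def test_truth_table_deletion_pins_input_low(self):
        # C loses its activator A: the marginalised rule reads A as absent
        net = build_network(
            ["A", "B", "C"],
            [("A", "C", "+"), ("B", "C", "-")],
            interpolation="boolecube",
        )
        cut = delete_connection(net, "A", "C")
        rule = cut.node("C").rule
        assert rule.inputs == ("B",)
        assert rule.outputs == (0, 0)  # (A or ...) & !B with A pinned to 0

    def test_delete_outgoing_of_sink_is_identity(self, toy, rng):
        pruned = delete_outgoing(toy, "F")
        assert structural_hash(pruned) == structural_hash(toy)
        states = rng.uniform(size=(50, len(toy.nodes)))
        assert np.allclose(
            CompiledNetwork(toy).derivative(states),
            CompiledNetwork(pruned).derivative(states),
        )

    def test_delete_outgoing_removes_self_loop_too(self, toy):
        pruned = delete_outgoing(toy, "B")
        assert pruned.out_degree("B") == 0
        assert not any(c.source == "B" for c in pruned.connections)
        assert len(pruned.connections) == len(toy.connections) - 3

    def test_operations_do_not_mutate_argument(self, toy):
        before = structural_hash(toy)
        delete_connection(toy, "B", "E")
        delete_outgoing(toy, "B")
        split_connection_input(toy, "B", "E")
        split_node_outputs(toy, "B")
        add_input_loops(toy)
        assert structural_hash(toy) == before


class TestSplits:
    def test_split_connection_preserves_counts(self, toy):
        split, name = split_connection_input(toy, "B", "E")
        assert len(split.nodes) == len(toy.nodes) + 1
        assert len(split.connections) == len(toy.connections)
        assert split.connection(name, "E").sign == toy.connection("B", "E").sign
        assert split.node(name).constant
        # B keeps its other outputs
        assert {c.target for c in split.outgoing("B")} == {"B", "C"}

    def test_split_missing_connection_raises(self, toy):
        with pytest.raises(NetworkValidationError):
            split_connection_input(toy, "A", "F")

    def test_double_split_uses_distinct_names(self, toy):
        once, n1 = split_connection_input(toy, "B", "E")
        twice, n2 = split_connection_input(once, "B", "C")
        assert n1 != n2
        assert twice.has_node(n1) and twice.has_node(n2)

    def test_split_node_reroutes_all_outputs(self, toy):
        split, name = split_node_outputs(toy, "B")
        assert split.out_degree("B") == 0
        assert {c.target for c in split.outgoing(name)} == {"B", "C", "E"}

    def test_split_node_can_keep_self_loop(self, toy):
        split, name = split_node_outputs(toy, "B", include_self_loop=False)
        assert {c.target for c in split.outgoing("B")} == {"B"}
        assert {c.target for c in split.outgoing(name)} == {"C", "E"}

    def test_split_sink_raises(self, toy):
        with pytest.raises(NetworkValidationError):
            split_node_outputs(toy, "F")


class TestInputLoops:
    def test_loop_added_only_to_inputs(self, toy):
        looped = add_input_loops(toy)
        assert looped.connection("A", "A").activating
        assert len(looped.connections) == len(toy.connections) + 1

    def test_network_without_inputs_unchanged(self, toggle):
        assert structural_hash(add_input_loops(toggle)) == structural_hash(toggle)

    def test_connection_count_grows_by_input_count(self):
        net = build_network(
            ["I1", "I2", "I3", "X"],
            [("I1", "X", "+"), ("I2", "X", "+"), ("I3", "X", "-")],
        )
        looped = add_input_loops(net)
        assert len(looped.connections) == len(net.connections) + 3


class TestTruthTable:
    def test_exhaustive_boolean_evaluation(self):
        rule = TruthTable(("x", "y"), (0, 1, 1, 1))  # OR
        assert [rule([a, b]) for a in (0, 1) for b in (0, 1)] == [0, 1, 1, 1]

    def test_fix_input_marginalises(self):
        rule = TruthTable(("x", "y"), (0, 0, 0, 1))  # AND
        assert rule.fix_input("x", 1).outputs == (0, 1)
        assert rule.fix_input("x", 0).outputs == (0, 0)

    def test_monotonicity_detection(self):
        and_rule = TruthTable(("x", "y"), (0, 0, 0, 1))
        xor_rule = TruthTable(("x", "y"), (0, 1, 1, 0))
        assert and_rule.monotonicity("x") == 1
        assert xor_rule.monotonicity("x") == 0
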