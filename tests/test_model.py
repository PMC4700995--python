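"""Network model, .bnet round-trips, rule evaluation and the synchronous step."""

from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bnfix import (
    And,
    BnetSyntaxError,
    Const,
    DuplicateNodeError,
    EmptyNetworkError,
    Iff,
    Not,
    PartialState,
    UndeclaredNodeError,
    Var,
    Xor,
    evaluate_rule,
    global_step,
    is_fixed_point,
    parse_bnet,
    write_bnet,
)
from conftest import random_network


class TestParse:
    def test_worked_example_structure(self, worked_example):
        net = worked_example
        assert net.nodes == ("v1", "v2", "v3", "v4", "v5", "v6")
        assert [net.indegree(v) for v in net.nodes] == [2, 1, 2, 2, 1, 1]
        assert net.max_indegree == 2
        assert net.regulators("v3") == {"v2", "v4"}

    def test_identity_self_loop(self):
        net = parse_bnet("a, a")
        assert net.n == 1
        assert net.regulators("a") == {"a"}
        assert net.max_indegree == 1

    def test_header_and_comments_skipped(self):
        net = parse_bnet("# comment\ntargets, factors\na, b | !b\nb, a\n")
        assert net.nodes == ("a", "b")

    @pytest.mark.parametrize(
        "text, err",
        [
            ("a, b", UndeclaredNodeError),
            ("a, 1\na, 0", DuplicateNodeError),
            ("", EmptyNetworkError),
            ("# just a comment", EmptyNetworkError),
            ("a, b &", BnetSyntaxError),
            ("a, (b", BnetSyntaxError),
            ("a b", BnetSyntaxError),
        ],
    )
    def test_errors_are_distinct_and_located(self, text, err):
        with pytest.raises(err) as e:
            parse_bnet(text)
        assert str(e.value)  # message-bearing

    def test_error_names_offending_line(self):
        with pytest.raises(BnetSyntaxError, match="line 2"):
            parse_bnet("a, 1\nb, a |\n")

    def test_precedence_not_and_or(self):
        net = parse_bnet("a, 1\nb, 1\nc, !a & b | a")
        # parsed as ((!a) & b) | a, which is 1 at a=1,b=0
        assert evaluate_rule(net.rules["c"], {"a": 1, "b": 0}) == 1
        assert evaluate_rule(net.rules["c"], {"a": 0, "b": 0}) == 0


def truth_table(expr, names):
    return [expr.evaluate(dict(zip(names, bits)))
            for bits in product((0, 1), repeat=len(names))]


class TestRoundTrip:
    def test_worked_example_round_trip(self, worked_example):
        net2 = parse_bnet(write_bnet(worked_example))
        assert net2.nodes == worked_example.nodes
        for v in worked_example.nodes:
            assert net2.regulators(v) == worked_example.regulators(v)
            names = sorted(worked_example.regulators(v))
            assert truth_table(net2.rules[v], names) == truth_table(
                worked_example.rules[v], names
            )

    def test_constant_node_round_trips(self):
        net = parse_bnet("a, 1")
        assert parse_bnet(write_bnet(net)).rules["a"].evaluate({}) == 1

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_random_network_round_trips_truth_tables(self, seed):
        net = random_network(seed, n=50, K=5)
        net2 = parse_bnet(write_bnet(net))
        assert net2.nodes == net.nodes
        for v in net.nodes:
            names = sorted(net.regulators(v))
            assert truth_table(net2.rules[v], names) == truth_table(
                net.rules[v], names
            ), v

    def test_xor_iff_render_to_core_operators(self):
        # programmatic AST with IFF/XOR must serialise into the ! & | dialect
        rules = {"a": Iff(Var("a"), Var("b")), "b": Xor(Var("a"), Var("b"))}
        from bnfix import BooleanNetwork

        net = BooleanNetwork(("a", "b"), rules)
        text = write_bnet(net)
        assert "<" not in text and "^" not in text
        net2 = parse_bnet(text)
        for v in net.nodes:
            assert truth_table(net2.rules[v], ["a", "b"]) == truth_table(
                net.rules[v], ["a", "b"]
            )


class TestEvaluate:
    @pytest.mark.parametrize(
        "expr, assignment, expected",
        [
            (Iff(Var("s5"), Var("s6")), {"s5": 0, "s6": 1}, 0),
            (And((Var("s2"), Var("s3"))), {"s2": 1, "s3": 1}, 1),
            (Not(Var("s5")), {"s5": 0}, 1),
            (Xor(Var("a"), Var("b")), {"a": 1, "b": 1}, 0),
            (Const(0), {}, 0),
        ],
    )
    def test_rule_semantics(self, expr, assignment, expected):
        assert evaluate_rule(expr, assignment) == expected

    def test_missing_reference_raises(self):
        with pytest.raises(KeyError):
            evaluate_rule(And((Var("a"), Var("b"))), {"a": 1})


class TestDynamics:
    def test_step_fixes_steady_state(self, worked_example):
        s = worked_example.state([0, 0, 0, 0, 0, 1])
        assert global_step(worked_example, s) == s

    def test_step_moves_non_steady_state(self, worked_example):
        s = worked_example.state([1, 1, 1, 1, 1, 1])
        assert global_step(worked_example, s).vector() == (1, 1, 1, 1, 1, 0)

    def test_negation_node_oscillates(self):
        net = parse_bnet("a, !a")
        assert global_step(net, net.state([0])).vector() == (1,)

    def test_is_fixed_point_examples(self, worked_example):
        assert is_fixed_point(worked_example, worked_example.state([1, 1, 1, 0, 1, 0]))
        assert not is_fixed_point(
            worked_example, worked_example.state([1, 1, 1, 1, 1, 1])
        )
        net = parse_bnet("a, a")
        assert is_fixed_point(net, net.state([0]))
        assert is_fixed_point(net, net.state([1]))

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), data=st.data())
    def test_step_total_deterministic_and_matches_rules(self, seed, data):
        """F(S) assigns every node, twice-computed results agree, and a
        state is fixed iff every rule reproduces its node's value."""
        net = random_network(seed, n=8, K=3)
        bits = data.draw(st.lists(st.integers(0, 1), min_size=8, max_size=8))
        s = net.state(bits)
        t1, t2 = global_step(net, s), global_step(net, s)
        assert t1 == t2
        assert t1.domain == set(net.nodes)
        assert is_fixed_point(net, s) == all(
            evaluate_rule(net.rules[v], s) == s[v] for v in net.nodes
        )


class TestPartialState:
    def test_equality_ignores_order(self):
        a = PartialState({"x": 1, "y": 0}, order=("x", "y"))
        b = PartialState({"y": 0, "x": 1}, order=("y", "x"))
        assert a == b and hash(a) == hash(b)
        assert a.vector() == (1, 0) and b.vector() == (0, 1)

    def test_order_must_cover_domain(self):
        with pytest.raises(ValueError):
            PartialState({"x": 1}, order=("x", "y"))
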