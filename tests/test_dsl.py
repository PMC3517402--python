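"""Model language: parsing, evaluation semantics, configuration."""

import math

import pytest
from hypothesis import given, strategies as st

from bkmc import (
    DslError,
    EvaluationError,
    evaluate_rate,
    make_fixture,
    parse_config,
    parse_expression,
    parse_model,
    serialize_model,
)
from bkmc.dsl import evaluate_expression, expression_to_source

NODE_C = """
node A { rate_up = 0.0; rate_down = 0.0; }
node B { rate_up = 0.0; rate_down = 0.0; }
node C {
  rate_up = B ? $kb : (A ? $ka : 0.0);
  rate_down = !(A & B) ? 1.0 : 0.0;
}
"""


def state_of(model, **bits):
    s = 0
    for name, v in bits.items():
        s |= int(v) << model.index[name]
    return s


class TestParseModel:
    def test_ternary_rate_block(self):
        model = parse_model(NODE_C)
        c = model.node("C")
        assert c.rate_up[0] == "ite"
        assert c.rate_down == ("ite", ("not", ("bin", "&", ("node", "A"), ("node", "B"))),
                               ("num", 1.0), ("num", 0.0))
        assert [n.name for n in model.nodes] == ["A", "B", "C"]

    def test_empty_source_rejected(self):
        with pytest.raises(DslError, match="no nodes"):
            parse_model("")

    def test_duplicate_node_name_rejected(self):
        with pytest.raises(DslError, match="duplicate"):
            parse_model("node B { rate_up = 1; rate_down = 1; }\n"
                        "node B { rate_up = 1; rate_down = 1; }")

    def test_undeclared_node_reference_rejected(self):
        with pytest.raises(DslError, match="undeclared node"):
            parse_model("node A { rate_up = Z ? 1 : 0; rate_down = 0; }")

    def test_syntax_error_reports_position(self):
        with pytest.raises(DslError, match=r"line 2"):
            parse_model("node A {\n rate_up = ?; rate_down = 0; }")

    def test_missing_rate_rejected(self):
        with pytest.raises(DslError, match="rate_down"):
            parse_model("node A { rate_up = 1; }")

    def test_comments_and_keyword_operators(self):
        model = parse_model(
            "# header comment\n"
            "node A { // trailing\n"
            "  rate_up = NOT A AND TRUE ? 2 : 0; rate_down = A OR FALSE ? 1 : 0;\n"
            "}\n"
        )
        assert evaluate_rate(model.nodes[0].rate_up, 0, {}, model) == 2.0

    def test_at_field_inlined(self):
        model = parse_model(
            "node A { logic = !A; rate_up = @logic ? 3 : 0; rate_down = @logic ? 0 : 5; }"
        )
        assert evaluate_rate(model.nodes[0].rate_up, 0, {}, model) == 3.0
        assert evaluate_rate(model.nodes[0].rate_down, 1, {}, model) == 5.0

    def test_circular_field_reference_rejected(self):
        with pytest.raises(DslError, match="circular"):
            parse_model("node A { x = @x; rate_up = @x; rate_down = 0; }")


class TestEvaluate:
    def test_conditional_speeds_idiom(self):
        # C activated by B at $kb, else by A at $ka, else not at all
        model = parse_model(NODE_C)
        expr = model.node("C").rate_up
        params = {"kb": 2.0, "ka": 0.5}
        assert evaluate_rate(expr, state_of(model, A=1, B=0), params, model) == 0.5
        assert evaluate_rate(expr, state_of(model, A=0, B=1), params, model) == 2.0
        assert evaluate_rate(expr, state_of(model, A=1, B=1), params, model) == 2.0
        assert evaluate_rate(expr, 0, params, model) == 0.0
        down = model.node("C").rate_down
        assert evaluate_rate(down, state_of(model, A=1, B=1), params, model) == 0.0
        assert evaluate_rate(down, 0, params, model) == 1.0

    def test_buffering_idiom(self):
        model = parse_model(
            "node A { rate_up = 0; rate_down = 0; }\n"
            "node B { rate_up = A ? 2.0 : 0.0; rate_down = A ? 0.0 : 0.001; }"
        )
        b = model.node("B")
        a_on = state_of(model, A=1)
        assert evaluate_rate(b.rate_up, a_on, {}, model) == 2.0
        assert evaluate_rate(b.rate_down, a_on, {}, model) == 0.0
        assert evaluate_rate(b.rate_down, 0, {}, model) == 0.001

    def test_two_level_idiom(self):
        # B reaches a second level B_h only while A persists
        model = parse_model(
            "node A { rate_up = 0; rate_down = 0; }\n"
            "node B { rate_up = A ? 1.0 : 0.0; rate_down = (A | B_h) ? 0.0 : 1.0; }\n"
            "node B_h { rate_up = (A & B) ? 1.0 : 0.0; rate_down = A ? 0.0 : 1.0; }"
        )
        s = state_of(model, A=1, B=1)
        assert evaluate_rate(model.node("B_h").rate_up, s, {}, model) == 1.0
        # with A gone, B holds while B_h is still on
        s2 = state_of(model, B=1, B_h=1)
        assert evaluate_rate(model.node("B").rate_down, s2, {}, model) == 0.0
        assert evaluate_rate(model.node("B_h").rate_down, s2, {}, model) == 1.0

    def test_negative_rate_is_error(self):
        model = parse_model("node A { rate_up = $ka - 1; rate_down = 0; }")
        with pytest.raises(EvaluationError, match="negative"):
            evaluate_rate(model.nodes[0].rate_up, 0, {"ka": 0.5}, model)

    def test_division_by_zero_is_error(self):
        expr = parse_expression("1 / A")
        model = parse_model("node A { rate_up = 0; rate_down = 0; }")
        with pytest.raises(EvaluationError, match="division"):
            evaluate_rate(expr, 0, {}, model)

    def test_unbound_parameter_is_error(self):
        model = parse_model("node A { rate_up = $missing; rate_down = 0; }")
        with pytest.raises(EvaluationError, match="unbound"):
            evaluate_rate(model.nodes[0].rate_up, 0, {}, model)

    def test_ternary_short_circuits_division(self):
        # the untaken branch would divide by zero
        expr = parse_expression("A ? 1.0 : 1 / A")
        model = parse_model("node A { rate_up = 0; rate_down = 0; }")
        assert evaluate_rate(expr, 1, {}, model) == 1.0

    @pytest.mark.parametrize(
        "src,expected",
        [
            ("1 + 2 * 3", 7.0),            # precedence
            ("(1 + 2) * 3", 9.0),
            ("2 < 3", 1.0),
            ("0.5 ^ 0", 1.0),              # nonzero is truthy
            ("!0.0", 1.0),
            ("1 == 1 ? 5 : 6", 5.0),
            ("2 - 3 - 1", -2.0),           # left associativity
            ("-2 + 3", 1.0),
            ("1 | 0 & 0", 1.0),            # AND binds tighter than OR
        ],
    )
    def test_operator_semantics(self, src, expected):
        assert evaluate_expression(parse_expression(src), 0, {}, {}) == expected


# -- round-trip property ----------------------------------------------------

_expr_leaf = st.one_of(
    st.floats(min_value=0, max_value=100, allow_nan=False).map(lambda v: ("num", float(v))),
    st.sampled_from(["A", "B", "C"]).map(lambda n: ("node", n)),
    st.sampled_from(["k1", "k2"]).map(lambda n: ("param", n)),
)


def _expr_tree(children):
    return st.one_of(
        st.tuples(st.just("not"), children),
        st.tuples(st.just("bin"), st.sampled_from(list("&|^+-*")), children, children),
        st.tuples(st.just("ite"), children, children, children),
    )


_exprs = st.recursive(_expr_leaf, _expr_tree, max_leaves=12)


@given(_exprs)
def test_expression_source_round_trip(expr):
    """Serializing any AST and reparsing yields the identical AST."""
    assert parse_expression(expression_to_source(expr)) == expr


@given(st.integers(0, 30), st.integers(2, 6))
def test_model_round_trip(seed, n):
    bnd, _ = make_fixture(f"random-{n}-node", seed=seed)
    model = parse_model(bnd)
    again = parse_model(serialize_model(model))
    assert [s.name for s in again.nodes] == [s.name for s in model.nodes]
    assert all(
        a.rate_up == b.rate_up and a.rate_down == b.rate_down
        for a, b in zip(again.nodes, model.nodes)
    )


@given(st.integers(0, 10), st.integers(0, 31))
def test_evaluation_is_pure(seed, state):
    bnd, _ = make_fixture("random-5-node", seed=seed)
    model = parse_model(bnd)
    for spec in model.nodes:
        v1 = evaluate_rate(spec.rate_up, state, {}, model)
        v2 = evaluate_rate(spec.rate_up, state, {}, model)
        assert v1 == v2 and math.isfinite(v1) and v1 >= 0


class TestParseConfig:
    def test_basic_fields(self):
        model = parse_model(NODE_C)
        cfg = parse_config(
            "timetick = 0.1; max_time = 4; sample_count = 50000;", model
        )
        assert cfg.timetick == 0.1 and cfg.max_time == 4 and cfg.sample_count == 50000

    def test_unknown_node_setting_rejected(self):
        model = parse_model(NODE_C)
        with pytest.raises(DslError, match="unknown node"):
            parse_config("timetick=1; max_time=2; Z.istate = 1;", model)

    def test_statdist_default_capped_by_sample_count(self):
        model = parse_model(NODE_C)
        cfg = parse_config("timetick=1; max_time=2; sample_count = 7;", model)
        assert cfg.statdist_traj_count == 7  # min(sample_count, default 100)
        cfg = parse_config("timetick=1; max_time=2; sample_count = 500;", model)
        assert cfg.statdist_traj_count == 100

    def test_statdist_count_above_sample_count_rejected(self):
        model = parse_model(NODE_C)
        with pytest.raises(DslError):
            parse_config(
                "timetick=1; max_time=2; sample_count=10; statdist_traj_count=20;",
                model,
            )

    def test_nonpositive_times_rejected(self):
        model = parse_model(NODE_C)
        with pytest.raises(DslError):
            parse_config("timetick = 0; max_time = 2;", model)
        with pytest.raises(DslError):
            parse_config("timetick = 1; max_time = -3;", model)

    def test_timetick_and_max_time_required(self):
        model = parse_model(NODE_C)
        with pytest.raises(DslError, match="explicit"):
            parse_config("sample_count = 10;", model)

    def test_node_settings_and_parameters_applied(self):
        model = parse_model(NODE_C)
        parse_config(
            "timetick=0.5; max_time=10;\n"
            "$ka = 0.5; $kb = 2;\n"
            "A.istate = 1; B.is_internal = TRUE; C.refstate = 0;",
            model,
        )
        assert model.parameters == {"ka": 0.5, "kb": 2.0}
        assert model.node("A").initial == "fixed-1" and model.node("A").is_input
        assert model.node("B").is_internal
        assert model.node("C").is_reference and model.node("C").reference_value == 0
        assert model.output_mask == 0b101
        assert model.reference_mask == 0b100
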