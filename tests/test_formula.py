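"""Formula DSL: grammar, evaluation, the definition dialogue, persistence."""

import math
import random

import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

import ontosim as o
from ontosim.errors import (
    DivisionByZeroError,
    DomainError,
    DuplicateNameError,
    FormulaSyntaxError,
    NoAnnotationsError,
    UnknownComponentError,
    ValidationError,
)
from ontosim.formula import (
    COMPONENTS,
    AlgorithmDefinition,
    BinOp,
    Component,
    Func,
    Neg,
    Num,
    bind_context,
    components_used,
    define_algorithm,
    evaluate,
    list_algorithms,
    load_algorithm,
    parse_formula,
    save_algorithm,
    to_text,
)

from conftest import LIN_FORMULA, RESNIK_FORMULA, make_random_session

RESNIK_ANSWERS = ["1", "No", RESNIK_FORMULA, "Resnik", "Yes"]


def naive_eval(ast, ctx, base=math.e):
    """Independent reference interpreter (plain python arithmetic, no guards)."""
    if isinstance(ast, Num):
        return ast.value
    if isinstance(ast, Component):
        return ctx[ast.name]
    if isinstance(ast, Neg):
        return -naive_eval(ast.operand, ctx, base)
    if isinstance(ast, Func):
        x = naive_eval(ast.operand, ctx, base)
        return math.log(x, base) if ast.name == "log" else math.sqrt(x)
    return {
        "+": lambda a, b: a + b,
        "-": lambda a, b: a - b,
        "*": lambda a, b: a * b,
        "/": lambda a, b: a / b,
        "^": lambda a, b: a ** b,
    }[ast.op](naive_eval(ast.left, ctx, base), naive_eval(ast.right, ctx, base))


class TestParsing:
    def test_negated_log_of_common_ancestor(self):
        assert parse_formula(RESNIK_FORMULA) == Neg(Func("log", Component("P.CommonAncestor")))

    def test_single_leaf(self):
        assert parse_formula("P.Node1") == Component("P.Node1")

    @pytest.mark.parametrize(
        "text,expected",
        [
            ("1+2*3", BinOp("+", Num(1.0), BinOp("*", Num(2.0), Num(3.0)))),
            ("(1+2)*3", BinOp("*", BinOp("+", Num(1.0), Num(2.0)), Num(3.0))),
            # unary minus binds tighter than * ...
            ("-2*3", BinOp("*", Neg(Num(2.0)), Num(3.0))),
            # ... but looser than ^
            ("-2^2", Neg(BinOp("^", Num(2.0), Num(2.0)))),
            # power is right-associative
            ("2^3^2", BinOp("^", Num(2.0), BinOp("^", Num(3.0), Num(2.0)))),
            ("2^-1", BinOp("^", Num(2.0), Neg(Num(1.0)))),
        ],
    )
    def test_precedence_and_associativity(self, text, expected):
        assert parse_formula(text) == expected

    def test_whitespace_insignificant(self):
        assert parse_formula(" - log( P.CommonAncestor ) ") == parse_formula(RESNIK_FORMULA)

    def test_unknown_identifier_named_in_error(self):
        with pytest.raises(UnknownComponentError, match="P.Bogus"):
            parse_formula("log(P.Bogus)")

    @pytest.mark.parametrize("bad", ["", "  ", "1+", "log(", "(1+2", "1 2", "log 3", "&"])
    def test_syntax_errors_carry_position(self, bad):
        with pytest.raises(FormulaSyntaxError) as exc:
            parse_formula(bad)
        assert exc.value.position >= 0

    def test_components_used_collects_leaves(self):
        ast = parse_formula(LIN_FORMULA)
        assert components_used(ast) == {"P.CommonAncestor", "P.Node1", "P.Node2"}


def ast_strategy(max_depth=4):
    leaf = st.one_of(
        st.integers(min_value=0, max_value=9).map(lambda n: Num(float(n))),
        st.sampled_from(sorted(COMPONENTS)).map(Component),
    )

    def extend(children):
        return st.one_of(
            st.tuples(st.sampled_from("+-*/^"), children, children).map(
                lambda t: BinOp(t[0], t[1], t[2])
            ),
            children.map(Neg),
            st.tuples(st.sampled_from(["log", "sqrt"]), children).map(
                lambda t: Func(t[0], t[1])
            ),
        )

    return st.recursive(leaf, extend, max_leaves=2 ** max_depth)


class TestRoundTripAndEvaluation:
    @given(ast=ast_strategy())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_print_parse_roundtrip(self, ast):
        assert parse_formula(to_text(ast)) == ast

    @given(ast=ast_strategy(), data=st.data())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_production_evaluator_matches_naive_interpreter(self, ast, data):
        ctx = {
            name: data.draw(
                st.floats(min_value=0.01, max_value=8.0), label=name
            )
            for name in components_used(ast)
        }
        try:
            expected = naive_eval(ast, ctx)
        except (ValueError, ZeroDivisionError, OverflowError):
            with pytest.raises((DomainError, DivisionByZeroError)):
                evaluate(ast, ctx, "e")
            return
        if isinstance(expected, complex) or not math.isfinite(expected):
            return
        assert evaluate(ast, ctx, "e") == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_resnik_of_probability_one_is_zero_in_every_base(self):
        ast = parse_formula(RESNIK_FORMULA)
        for base in ("e", "2", "10"):
            assert evaluate(ast, {"P.CommonAncestor": 1.0}, base) == 0.0

    def test_log_of_zero_is_domain_error(self):
        ast = parse_formula(RESNIK_FORMULA)
        with pytest.raises(DomainError):
            evaluate(ast, {"P.CommonAncestor": 0.0}, "e")

    def test_log_base_changes_value(self):
        ast = parse_formula("log(P.Node1)")
        ctx = {"P.Node1": 8.0}
        assert evaluate(ast, ctx, "2") == pytest.approx(3.0)
        assert evaluate(ast, ctx, "10") == pytest.approx(math.log10(8.0))
        assert evaluate(ast, ctx, "e") == pytest.approx(math.log(8.0))

    def test_division_by_zero_reported(self):
        ast = parse_formula("1/(P.Node1-P.Node1)")
        with pytest.raises(DivisionByZeroError):
            evaluate(ast, {"P.Node1": 0.5}, "e")

    def test_lin_formula_matches_hand_coded_ratio_on_random_contexts(self):
        ast = parse_formula(LIN_FORMULA)
        rng = random.Random(0)
        for _ in range(100):
            p1, p2, pc = (rng.uniform(1e-6, 0.999) for _ in range(3))
            ctx = {"P.Node1": p1, "P.Node2": p2, "P.CommonAncestor": pc}
            expected = 2 * math.log(pc) / (math.log(p1) + math.log(p2))
            assert evaluate(ast, ctx, "e") == pytest.approx(expected, rel=1e-12)


class TestBindContext:
    def test_worked_pair_binds_root_probability_one(self, annotated_diamond):
        dag, _, _ = annotated_diamond
        alg = AlgorithmDefinition.from_formula("Resnik", RESNIK_FORMULA)
        ctx = bind_context(dag, "GO:0000003", "GO:0000006", alg)
        assert ctx == {"P.CommonAncestor": 1.0}

    def test_self_pair_shortest_distance_zero(self, annotated_diamond):
        dag, _, _ = annotated_diamond
        alg = AlgorithmDefinition.from_formula("d", "Distance.Shortest")
        ctx = bind_context(dag, "GO:0000005", "GO:0000005", alg)
        assert ctx["Distance.Shortest"] == 0.0

    def test_binding_is_lazy_outside_components_used(self, diamond_dag):
        # purely structural formula on an unannotated DAG: no probability work
        alg = AlgorithmDefinition.from_formula("depths", "Depth.Node1+Depth.Node2")
        ctx = bind_context(diamond_dag, "GO:0000003", "GO:0000005", alg)
        assert ctx == {"Depth.Node1": 1.0, "Depth.Node2": 2.0}

    def test_p_component_on_unannotated_dag_raises(self, diamond_dag):
        alg = AlgorithmDefinition.from_formula("p1", "P.Node1")
        with pytest.raises(NoAnnotationsError):
            bind_context(diamond_dag, "GO:0000003", "GO:0000006", alg)

    def test_every_component_binds_on_annotated_dag(self):
        dag, _, _, _ = make_random_session(seed=12)
        formula = "+".join(sorted(COMPONENTS))
        alg = AlgorithmDefinition.from_formula("all", formula)
        ids = sorted(dag.terms)
        ctx = bind_context(dag, ids[3], ids[7], alg)
        assert set(ctx) == COMPONENTS
        for name, value in ctx.items():
            if name.startswith("P."):
                assert 0.0 <= value <= 1.0
            else:
                assert value >= 0.0


class TestDefinitionDialogue:
    def test_published_transcript_defines_resnik(self):
        alg = define_algorithm(RESNIK_ANSWERS)
        assert alg is not None
        assert alg.name == "Resnik"
        assert alg.formula_text == RESNIK_FORMULA
        assert alg.components == {"P.CommonAncestor"}

    def test_group_names_accepted_in_place_of_menu_numbers(self):
        alg = define_algorithm(["CommonAncestor", "No", RESNIK_FORMULA, "R2", "Yes"])
        assert alg is not None and alg.name == "R2"

    def test_component_loop_collects_several_groups(self):
        alg = define_algorithm(["2", "Yes", "3", "Yes", "1", "No", LIN_FORMULA, "Lin", "Yes"])
        assert alg is not None
        assert alg.components == {"P.Node1", "P.Node2", "P.CommonAncestor"}

    def test_non_confirmation_stores_nothing(self):
        assert define_algorithm(["1", "No", RESNIK_FORMULA, "Resnik", "No"]) is None

    def test_undeclared_component_rejected_by_name(self):
        with pytest.raises(ValidationError, match="P.Node2"):
            define_algorithm(["2", "No", "log(P.Node2)", "bad", "Yes"])

    def test_duplicate_name_rejected(self):
        with pytest.raises(DuplicateNameError):
            define_algorithm(RESNIK_ANSWERS, existing_names=["Resnik"])

    def test_truncated_transcript_rejected(self):
        with pytest.raises(ValidationError, match="ended early"):
            define_algorithm(["1", "No", RESNIK_FORMULA])


class TestAlgorithmStore:
    def test_resnik_roundtrip_is_fixpoint(self, tmp_path):
        alg = define_algorithm(RESNIK_ANSWERS)
        save_algorithm(alg, tmp_path)
        loaded = load_algorithm("Resnik", tmp_path)
        assert loaded == alg
        save_algorithm(loaded, tmp_path)
        assert load_algorithm("Resnik", tmp_path) == loaded

    def test_missing_formula_line_is_corrupt(self, tmp_path):
        (tmp_path / "Broken.alg").write_text("name: Broken\nlog_base: e\n")
        with pytest.raises(o.errors.CorruptFileError):
            load_algorithm("Broken", tmp_path)

    def test_missing_file_not_found(self, tmp_path):
        with pytest.raises(o.errors.NotFoundError):
            load_algorithm("nope", tmp_path)

    def test_unsafe_names_percent_encoded(self, tmp_path):
        alg = AlgorithmDefinition.from_formula("a/b c", "P.Node1")
        path = save_algorithm(alg, tmp_path)
        assert "/" not in path.rsplit("/", 1)[-1].replace(".alg", "")
        assert load_algorithm("a/b c", tmp_path) == alg
        assert list_algorithms(tmp_path) == ["a/b c"]

    @given(ast=ast_strategy(), data=st.data())
    @settings(
        max_examples=20,
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    def test_random_algorithms_roundtrip_and_evaluate_identically(self, tmp_path, ast, data):
        alg = AlgorithmDefinition.from_formula("gen", to_text(ast))
        save_algorithm(alg, tmp_path)
        loaded = load_algorithm("gen", tmp_path)
        assert loaded.ast == alg.ast
        for i in range(50):
            ctx = {
                name: data.draw(st.floats(min_value=0.01, max_value=4.0), label=f"{name}#{i}")
                for name in alg.components
            }
            try:
                a = evaluate(alg.ast, ctx, alg.log_base)
            except (DomainError, DivisionByZeroError) as exc:
                with pytest.raises(type(exc)):
                    evaluate(loaded.ast, ctx, loaded.log_base)
                continue
            assert evaluate(loaded.ast, ctx, loaded.log_base) == a
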