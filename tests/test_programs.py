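"""Generator language: parsing, evaluation, random creation, mutation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netevo.programs import (OPERATORS, GeneratorProgram, ProgramNode,
                             ProgramSyntaxError, affinity, mutate, parse,
                             program_length, random_program)

_terminals = st.one_of(
    st.sampled_from(["i", "j", "k", "k'", "d", "d_D", "d_R"]).map(
        ProgramNode.var),
    st.floats(min_value=-1e6, max_value=1e6, allow_nan=False).map(
        ProgramNode.const),
)


def _node_trees():
    return st.recursive(
        _terminals,
        lambda children: st.sampled_from(sorted(OPERATORS)).flatmap(
            lambda sym: st.tuples(*[children] * OPERATORS[sym]).map(
                lambda args: ProgramNode.op(sym, *args))),
        max_leaves=25,
    )


class TestEvaluation:
    @pytest.mark.parametrize("text, ctx, expected", [
        ("j", {"j": 5}, 5.0),
        ("(psi 2 1.0 0.0)", {"i": 4, "j": 6}, 1.0),   # 4 mod 2 == 6 mod 2
        ("(psi 2 1.0 0.0)", {"i": 4, "j": 7}, 0.0),
        ("(/ 1 k)", {"k": 0}, 0.0),                   # protected division
        ("(/ 6 k)", {"k": 3}, 2.0),
        ("(log k)", {"k": 0}, 0.0),                   # protected log
        ("(log 0)", {}, 0.0),
        ("(+ k (* 2 k'))", {"k": 1, "k'": 3}, 7.0),
        ("(max 2 (min i j))", {"i": 9, "j": 4}, 4.0),
        ("(gt i j 10 20)", {"i": 3, "j": 1}, 10.0),
        ("(lt i j 10 20)", {"i": 3, "j": 1}, 20.0),
        ("(eq i j 1 0)", {"i": 3, "j": 3}, 1.0),
        ("(eq0 k 5 7)", {"k": 0}, 5.0),
        ("(eq0 k 5 7)", {"k": 2}, 7.0),
        ("(abs (- 2 7))", {}, 5.0),
    ])
    def test_scalar_examples(self, text, ctx, expected):
        assert parse(text).evaluate(ctx) == expected

    def test_vectorized_matches_scalar(self):
        program = parse("(+ (/ k' i) (psi 3 2 1))")
        ks = np.array([0.0, 1.0, 5.0])
        ids = np.array([1.0, 3.0, 6.0])
        js = np.array([4.0, 6.0, 9.0])
        batch = program.evaluate({"k'": ks, "i": ids, "j": js})
        singles = [program.evaluate({"k'": k, "i": i, "j": j})
                   for k, i, j in zip(ks, ids, js)]
        assert np.allclose(batch, singles)

    def test_evaluation_is_pure(self):
        program = parse("(pow (+ i 1) (/ k' 3))")
        ctx = {"i": 7.0, "k'": 11.0}
        assert program.evaluate(ctx) == program.evaluate(ctx)

    def test_protected_everywhere(self, rng):
        """Random programs on huge contexts never leak NaN or infinity."""
        for _ in range(300):
            program = random_program(rng, directed=True, max_depth=4)
            ctx = {v: rng.uniform(0, 1e6) for v in
                   ("i", "j", "k", "k'", "d", "d_D", "d_R")}
            value = program.evaluate(ctx)
            assert np.isfinite(value)

    def test_overflow_is_clamped(self):
        big = parse("(* (pow 10 300) (pow 10 300))")
        assert np.isfinite(big.evaluate({}))
        assert abs(big.evaluate({})) <= 1e300


class TestAffinity:
    @pytest.mark.parametrize("i, j, g, expected", [
        (3, 7, 2, 10.0),    # both odd
        (2, 5, 2, 1.0),     # parities differ
        (4, 6, 2, 10.0),
    ])
    def test_examples(self, i, j, g, expected):
        assert affinity(i, j, g, 10.0, 1.0) == expected

    def test_congruence_shift(self):
        for x in range(1, 30):
            assert affinity(x, x + 6, 6, 42.0, 0.0) == 42.0

    def test_single_group_when_g_small(self):
        assert affinity(2, 9, 1, 5.0, 0.0) == 5.0
        assert affinity(2, 9, 0.8, 5.0, 0.0) == 5.0  # truncation

    def test_same_group_is_equivalence_relation(self):
        g = 4
        ids = range(1, 25)
        same = lambda a, b: affinity(a, b, g, 1.0, 0.0) == 1.0
        assert all(same(a, a) for a in ids)
        assert all(same(b, a) for a in ids for b in ids if same(a, b))
        for a in ids:
            for b in ids:
                for c in ids:
                    if same(a, b) and same(b, c):
                        assert same(a, c)


class TestParseFormat:
    @pytest.mark.parametrize("text", [
        "k'", "(/ 1 i)", "(+ k 1)", "(psi 4 10 1)",
        "(gt (+ i j) 3 k' 0.5)", "(exp (log (abs d)))",
    ])
    def test_round_trip_text(self, text):
        program = parse(text)
        assert parse(program.format()).root == program.root

    def test_round_trip_random(self, rng):
        for _ in range(300):
            program = random_program(rng, directed=bool(rng.integers(2)))
            again = parse(program.format(), directed=program.directed)
            assert again.root == program.root
            assert again.format() == program.format()

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(_node_trees())
    def test_round_trip_arbitrary_trees(self, root):
        program = GeneratorProgram(root, directed=True)
        again = parse(program.format(), directed=True)
        assert again.root == program.root

    def test_unicode_psi_accepted(self):
        assert parse("(ψ 2 1 0)").root == parse("(psi 2 1 0)").root

    @pytest.mark.parametrize("bad", ["k + ", "(+ k", "(+ k 1 2)", "(foo 1 2)",
                                     "", "qq", "(psi 1 2)"])
    def test_syntax_errors(self, bad):
        with pytest.raises(ProgramSyntaxError):
            parse(bad)

    def test_mode_legality_checked_at_construction(self):
        with pytest.raises(ValueError, match="undirected"):
            parse("d_D", directed=False)
        with pytest.raises(ValueError, match="undirected"):
            parse("(+ d_R 1)", directed=False)
        parse("(+ k (+ k' d))", directed=False)  # k, k', d stay legal

    def test_infix_rendering(self):
        assert parse("(+ k 1)").to_infix() == "(k + 1)"
        assert parse("(psi 2 1 0)").to_infix() == "ψ(2, 1, 0)"


class TestLength:
    @pytest.mark.parametrize("text, expected", [
        ("3.5", 1),
        ("(+ k 1)", 3),
        ("(psi 2 1 0)", 4),
        ("(gt i j 1 0)", 5),
    ])
    def test_node_counts(self, text, expected):
        assert program_length(parse(text)) == expected


class TestRandomAndMutate:
    def test_random_program_deterministic(self):
        a = random_program(np.random.default_rng(7))
        b = random_program(np.random.default_rng(7))
        assert a.root == b.root

    def test_random_programs_valid_and_bounded(self, rng):
        for _ in range(500):
            depth = int(rng.integers(1, 6))
            program = random_program(rng, directed=False, max_depth=depth)
            assert program.root.depth <= depth
            # construction re-validates arity and mode legality
            GeneratorProgram(program.root, directed=False)

    def test_mutation_reproducible_and_valid(self, rng):
        parent = parse("(+ (/ k' i) 1)")
        child_a = mutate(parent, np.random.default_rng(11))
        child_b = mutate(parent, np.random.default_rng(11))
        assert child_a.root == child_b.root
        for _ in range(500):
            child = mutate(parent, rng)
            GeneratorProgram(child.root, directed=child.directed)
        assert parent.format() == "(+ (/ k' i) 1)"  # parent untouched

    def test_mutation_is_single_subtree_splice(self):
        parent = parse("(+ k 1)")
        donor = ProgramNode.var("j")
        child = parent.replace_subtree(2, donor)  # the "1" leaf
        assert child.format() == "(+ k j)"

    def test_mutation_respects_size_cap(self, rng):
        parent = parse("(+ k 1)")
        for _ in range(200):
            assert len(mutate(parent, rng, max_size=30)) <= 30
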