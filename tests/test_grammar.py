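"""Grammar construction, derivation sampling and the enumeration oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cvgrn.grammar import (
    DepthError,
    DerivationTree,
    EnumerationCapError,
    Grammar,
    GrammarError,
    default_grammar,
    enumerate_sentences,
    random_derivation,
    tree_yield,
    validate_tree,
)

from conftest import e_var, leaf, s_tree, sin_plus_cos_minus


class TestGrammarConstruction:
    def test_quadruple_invariants(self):
        g = default_grammar(3)
        assert not (g.nonterminals & g.terminals)
        assert g.start <= g.nonterminals
        for p in g.productions:
            assert p.lhs in g.nonterminals
            assert all(s in g.nonterminals | g.terminals for s in p.rhs)
        # every nonterminal productive: min heights are finite
        for nt in g.nonterminals:
            assert g.min_height(nt) >= 2

    def test_rejects_bad_gene_count(self):
        with pytest.raises(GrammarError):
            default_grammar(0)

    def test_single_variable_grammar(self):
        g = default_grammar(1)
        var_prods = g.productions_for("var")
        assert [p.rhs for p in var_prods] == [("x_1",)]
        assert enumerate_sentences(g, 4) == {("x_1",)}

    def test_overlapping_symbol_sets_rejected(self):
        with pytest.raises(GrammarError):
            Grammar({"a"}, {"a"}, [("a", ("a",))], {"a"})

    def test_unproductive_nonterminal_rejected(self):
        # b only rewrites to itself and can never reach a terminal
        with pytest.raises(GrammarError, match="unproductive"):
            Grammar({"a", "b"}, {"t"}, [("a", ("t",)), ("b", ("b",))], {"a"})

    def test_text_round_trip(self):
        g = default_grammar(2)
        g2 = Grammar.from_text(g.to_text())
        assert set(g2.productions) == set(g.productions)
        assert g2.terminals == g.terminals
        assert g2.start == {"s"}


class TestDerivedTreeOfTheWorkedExample:
    """'sin z + cos z - z' must be derivable, with the expected structure."""

    def test_validates_and_yields(self):
        g = default_grammar(1, var_names=["z"])
        t = sin_plus_cos_minus("z")
        assert validate_tree(g, t)
        assert tree_yield(t) == ["sin", "z", "+", "cos", "z", "-", "z"]

    def test_production_usage(self):
        t = sin_plus_cos_minus("z")
        shapes = []

        def walk(n):
            if not n.is_leaf:
                shapes.append((n.symbol, tuple(c.symbol for c in n.children)))
                for c in n.children:
                    walk(c)

        walk(t)
        assert shapes.count(("expr", ("expr", "op", "expr"))) == 2
        assert shapes.count(("expr", ("pre", "expr"))) == 2
        assert shapes.count(("var", ("z",))) == 3

    def test_same_sentence_under_multivariable_grammar(self):
        g = default_grammar(6)
        t = sin_plus_cos_minus("x_1")
        assert validate_tree(g, t)
        assert tree_yield(t) == ["sin", "x_1", "+", "cos", "x_1", "-", "x_1"]


class TestRandomDerivation:
    def test_minimal_depth_forces_shortest_derivation(self, rng):
        g = default_grammar(3)
        t = random_derivation(g, 4, rng)
        assert t.depth == 4
        assert t.symbol == "s"
        assert t.children[0].symbol == "expr"
        assert t.children[0].children[0].symbol == "var"
        assert tree_yield(t)[0] in {"x_1", "x_2", "x_3"}

    def test_depth_below_minimum_raises(self, rng):
        with pytest.raises(DepthError):
            random_derivation(default_grammar(2), 3, rng)

    def test_same_seed_same_tree(self):
        g = default_grammar(2)
        t1 = random_derivation(g, 7, np.random.default_rng(9))
        t2 = random_derivation(g, 7, np.random.default_rng(9))
        assert t1 == t2

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), depth=st.integers(4, 8))
    def test_always_valid_within_depth(self, seed, depth):
        g = default_grammar(2)
        t = random_derivation(g, depth, np.random.default_rng(seed))
        assert validate_tree(g, t)
        assert t.depth <= depth

    def test_sampled_yields_within_enumeration(self, rng):
        g = default_grammar(2)
        universe = enumerate_sentences(g, 6)
        for _ in range(500):
            t = random_derivation(g, 6, rng)
            assert tuple(tree_yield(t)) in universe


class TestValidateTree:
    def test_leaf_with_nonterminal_symbol_is_invalid(self):
        g = default_grammar(1)
        assert not validate_tree(g, s_tree(DerivationTree("expr")))

    def test_wrong_production_shape_is_invalid(self):
        g = default_grammar(1)
        bad = DerivationTree("expr", (e_var("x_1"), e_var("x_1")))
        assert not validate_tree(g, bad)

    def test_bare_terminal_leaf_is_valid(self):
        g = default_grammar(1)
        assert validate_tree(g, leaf("x_1"))
        assert tree_yield(leaf("x_1")) == ["x_1"]


class TestEnumeration:
    def test_contains_expected_small_sentences(self):
        g = default_grammar(2)
        s5 = enumerate_sentences(g, 5)
        assert ("x_1", "+", "x_2") in s5
        assert ("cos", "x_2") in s5

    def test_monotone_in_depth(self):
        g = default_grammar(2)
        assert enumerate_sentences(g, 4) <= enumerate_sentences(g, 5)
        assert enumerate_sentences(g, 5) <= enumerate_sentences(g, 6)

    def test_matches_independent_recursive_expansion(self):
        """Second, hand-written expansion of the m=1 grammar."""

        def oracle(sym: str, budget: int) -> set[tuple[str, ...]]:
            terminals = {"sin", "cos", "+", "-", "*", "/", "x_1"}
            if sym in terminals:
                return {(sym,)} if budget >= 1 else set()
            rules = {
                "s": [("expr",)],
                "expr": [("expr", "op", "expr"), ("pre", "expr"), ("var",)],
                "pre": [("sin",), ("cos",)],
                "op": [("+",), ("-",), ("*",), ("/",)],
                "var": [("x_1",)],
            }
            out: set[tuple[str, ...]] = set()
            if budget < 2:
                return out
            for rhs in rules[sym]:
                partials: list[tuple[str, ...]] = [()]
                for child in rhs:
                    exts = oracle(child, budget - 1)
                    partials = [p + e for p in partials for e in exts]
                    if not partials:
                        break
                out |= set(partials)
            return out

        g = default_grammar(1)
        for depth in (4, 5, 6):
            assert enumerate_sentences(g, depth) == oracle("s", depth)

    def test_cap_guard(self):
        g = default_grammar(4)
        with pytest.raises(EnumerationCapError):
            enumerate_sentences(g, 7, cap=1000)

    def test_yield_length_equals_leaf_count(self, rng):
        g = default_grammar(3)
        for _ in range(50):
            t = random_derivation(g, 7, rng)

            def count_leaves(n):
                return 1 if n.is_leaf else sum(count_leaves(c) for c in n.children)

            assert len(tree_yield(t)) == count_leaves(t)
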