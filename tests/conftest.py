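"""Shared helpers: compact derivation-tree builders for the expression grammar."""

from __future__ import annotations

import numpy as np
import pytest

from cvgrn.grammar import DerivationTree


def leaf(symbol: str) -> DerivationTree:
    return DerivationTree(symbol)


def var_node(name: str) -> DerivationTree:
    return DerivationTree("var", (leaf(name),))


def e_var(name: str) -> DerivationTree:
    """expr -> var -> name"""
    return DerivationTree("expr", (var_node(name),))


def e_pre(fn: str, child: DerivationTree) -> DerivationTree:
    """expr -> pre child"""
    return DerivationTree("expr", (DerivationTree("pre", (leaf(fn),)), child))


def e_bin(left: DerivationTree, op: str, right: DerivationTree) -> DerivationTree:
    """expr -> left op right"""
    return DerivationTree("expr", (left, DerivationTree("op", (leaf(op),)), right))


def s_tree(expr: DerivationTree) -> DerivationTree:
    return DerivationTree("s", (expr,))


def sin_plus_cos_minus(var: str) -> DerivationTree:
    """The derivation of 'sin v + cos v - v' (left-associated)."""
    return s_tree(
        e_bin(
            e_bin(e_pre("sin", e_var(var)), "+", e_pre("cos", e_var(var))),
            "-",
            e_var(var),
        )
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
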