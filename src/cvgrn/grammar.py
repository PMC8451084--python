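"""Context-free grammar machinery for ODE right-hand-side expressions.

A gene's dynamics are written as an algebraic expression over the gene
variables x_1 … x_m, trigonometric primitives and the four arithmetic
operators.  The expression language is a context-free grammar
G = (N, T, P, S); candidate model structures are derivation trees of G,
which makes every individual produced by the genetic search syntactically
valid by construction.

Derivation-tree depth is counted in node levels: the shortest complete
derivation s → expr → var → x_k has depth 4.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Grammar",
    "GrammarError",
    "DepthError",
    "EnumerationCapError",
    "Production",
    "DerivationTree",
    "default_grammar",
    "random_derivation",
    "validate_tree",
    "tree_yield",
    "enumerate_sentences",
]


class GrammarError(ValueError):
    """Malformed grammar or grammar operation."""


class DepthError(GrammarError):
    """Requested depth cannot accommodate any complete derivation."""


class EnumerationCapError(GrammarError):
    """Sentence enumeration would exceed the configured cap."""


@dataclass(frozen=True)
class Production:
    """One rewrite rule lhs -> rhs[0] rhs[1] ..."""

    lhs: str
    rhs: tuple[str, ...]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.lhs} -> {' '.join(self.rhs)}"


class Grammar:
    """A context-free grammar quadruple (N, T, P, S).

    Invariants enforced at construction: N and T are disjoint, every start
    symbol is a nonterminal, production sides draw only from N and N ∪ T,
    and every nonterminal is productive (derives a terminal-only string in
    finite depth).
    """

    def __init__(
        self,
        nonterminals: Iterable[str],
        terminals: Iterable[str],
        productions: Iterable[Production | tuple[str, Sequence[str]]],
        start: Iterable[str],
    ) -> None:
        self.nonterminals = frozenset(nonterminals)
        self.terminals = frozenset(terminals)
        self.productions = tuple(
            p if isinstance(p, Production) else Production(p[0], tuple(p[1]))
            for p in productions
        )
        self.start = frozenset(start)

        if self.nonterminals & self.terminals:
            raise GrammarError(
                f"nonterminals and terminals overlap: "
                f"{sorted(self.nonterminals & self.terminals)}"
            )
        if not self.start <= self.nonterminals:
            raise GrammarError("start symbols must be nonterminals")
        symbols = self.nonterminals | self.terminals
        for p in self.productions:
            if p.lhs not in self.nonterminals:
                raise GrammarError(f"production lhs {p.lhs!r} is not a nonterminal")
            if not p.rhs:
                raise GrammarError(f"empty rhs for {p.lhs!r} (ε-rules unsupported)")
            for s in p.rhs:
                if s not in symbols:
                    raise GrammarError(f"unknown symbol {s!r} in production {p}")

        self._by_lhs: dict[str, tuple[Production, ...]] = {}
        for p in self.productions:
            self._by_lhs.setdefault(p.lhs, ())
            self._by_lhs[p.lhs] += (p,)
        self._production_set = frozenset(self.productions)
        self._min_height = self._compute_min_heights()

    def _compute_min_heights(self) -> dict[str, int]:
        h: dict[str, int] = {t: 1 for t in self.terminals}
        changed = True
        while changed:
            changed = False
            for p in self.productions:
                if all(s in h for s in p.rhs):
                    cand = 1 + max(h[s] for s in p.rhs)
                    if cand < h.get(p.lhs, np.inf):
                        h[p.lhs] = cand
                        changed = True
        dead = self.nonterminals - h.keys()
        if dead:
            raise GrammarError(f"unproductive nonterminals: {sorted(dead)}")
        return h

    # -- queries ----------------------------------------------------------

    def productions_for(self, symbol: str) -> tuple[Production, ...]:
        return self._by_lhs.get(symbol, ())

    def min_height(self, symbol: str) -> int:
        """Depth (node levels) of the shallowest complete subtree at symbol."""
        return self._min_height[symbol]

    def is_terminal(self, symbol: str) -> bool:
        return symbol in self.terminals

    def has_production(self, lhs: str, rhs: Sequence[str]) -> bool:
        return Production(lhs, tuple(rhs)) in self._production_set

    # -- plain-text serialization ----------------------------------------

    def to_text(self) -> str:
        """One production per line, ``lhs -> sym sym ...``."""
        return "\n".join(str(p) for p in self.productions) + "\n"

    @classmethod
    def from_text(cls, text: str, start: Iterable[str] | None = None) -> "Grammar":
        """Parse a production file.

        Terminals are the symbols that never occur on a left-hand side.
        If ``start`` is not given, the first production's lhs is used.
        """
        productions: list[Production] = []
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "->" not in line:
                raise GrammarError(f"line {lineno}: missing '->'")
            lhs, _, rhs = line.partition("->")
            lhs = lhs.strip()
            rhs_syms = tuple(rhs.split())
            if not lhs or not rhs_syms:
                raise GrammarError(f"line {lineno}: malformed production")
            productions.append(Production(lhs, rhs_syms))
        if not productions:
            raise GrammarError("no productions found")
        nonterminals = {p.lhs for p in productions}
        terminals = {s for p in productions for s in p.rhs} - nonterminals
        if start is None:
            start = {productions[0].lhs}
        return cls(nonterminals, terminals, productions, start)


@dataclass(frozen=True)
class DerivationTree:
    """A (sub)derivation: a symbol with the ordered children it rewrote to.

    Leaves carry terminal symbols; an internal node together with its
    children's symbols must match exactly one production of the grammar.
    """

    symbol: str
    children: tuple["DerivationTree", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def depth(self) -> int:
        """Height in node levels (a lone leaf has depth 1)."""
        if not self.children:
            return 1
        return 1 + max(c.depth for c in self.children)

    @property
    def n_nodes(self) -> int:
        return 1 + sum(c.n_nodes for c in self.children)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return " ".join(tree_yield(self))


def default_grammar(m: int, var_names: Sequence[str] | None = None) -> Grammar:
    """The expression grammar over ``m`` gene variables.

    Nonterminals {s, expr, op, pre, var}; terminals are sin, cos, the four
    arithmetic operators and the variables x_1 … x_m (or ``var_names``).
    Integer powers are expressed as repeated multiplication.
    """
    if m < 1:
        raise GrammarError(f"gene count must be >= 1, got {m}")
    if var_names is None:
        var_names = [f"x_{k}" for k in range(1, m + 1)]
    elif len(var_names) != m:
        raise GrammarError("var_names length must equal m")
    productions: list[tuple[str, tuple[str, ...]]] = [
        ("s", ("expr",)),
        ("expr", ("expr", "op", "expr")),
        ("expr", ("pre", "expr")),
        ("expr", ("var",)),
        ("pre", ("sin",)),
        ("pre", ("cos",)),
        ("op", ("+",)),
        ("op", ("-",)),
        ("op", ("*",)),
        ("op", ("/",)),
    ]
    productions += [("var", (v,)) for v in var_names]
    terminals = {"sin", "cos", "+", "-", "*", "/"} | set(var_names)
    return Grammar({"s", "expr", "op", "pre", "var"}, terminals, productions, {"s"})


def _pick_start(g: Grammar, rng: np.random.Generator) -> str:
    starts = sorted(g.start)
    if len(starts) == 1:
        return starts[0]
    return starts[int(rng.integers(len(starts)))]


def random_derivation(
    g: Grammar,
    max_depth: int,
    rng: np.random.Generator,
    symbol: str | None = None,
) -> DerivationTree:
    """Draw a uniform-by-production random derivation tree of depth <= max_depth.

    At each node, productions are chosen uniformly among those that can
    still complete within the remaining depth budget; this guarantees
    termination.  ``symbol`` defaults to the grammar's start symbol.
    """
    if symbol is None:
        symbol = _pick_start(g, rng)
    if max_depth < g.min_height(symbol):
        raise DepthError(
            f"max_depth={max_depth} below minimal completion depth "
            f"{g.min_height(symbol)} of {symbol!r}"
        )

    def expand(sym: str, budget: int) -> DerivationTree:
        if g.is_terminal(sym):
            return DerivationTree(sym)
        eligible = [
            p
            for p in g.productions_for(sym)
            if 1 + max(g.min_height(s) for s in p.rhs) <= budget
        ]
        if not eligible:  # pragma: no cover - excluded by the top-level check
            raise DepthError(f"no production of {sym!r} completes in depth {budget}")
        p = eligible[int(rng.integers(len(eligible)))]
        return DerivationTree(sym, tuple(expand(s, budget - 1) for s in p.rhs))

    return expand(symbol, max_depth)


def validate_tree(g: Grammar, t: DerivationTree) -> bool:
    """True iff every leaf is terminal and every internal node matches a production."""
    if t.is_leaf:
        return t.symbol in g.terminals
    if t.symbol not in g.nonterminals:
        return False
    if not g.has_production(t.symbol, [c.symbol for c in t.children]):
        return False
    return all(validate_tree(g, c) for c in t.children)


def tree_yield(t: DerivationTree) -> list[str]:
    """Left-to-right terminal leaf sequence (the derived sentence)."""
    if t.is_leaf:
        return [t.symbol]
    out: list[str] = []
    for c in t.children:
        out.extend(tree_yield(c))
    return out


def enumerate_sentences(
    g: Grammar,
    max_depth: int,
    symbol: str | None = None,
    cap: int = 200_000,
) -> set[tuple[str, ...]]:
    """Exact set of yields of all complete derivations of depth <= max_depth.

    Test oracle for the random sampler; refuses (EnumerationCapError) when
    production fan-out would push the set past ``cap``.
    """
    memo: dict[tuple[str, int], frozenset[tuple[str, ...]]] = {}

    def sentences(sym: str, budget: int) -> frozenset[tuple[str, ...]]:
        key = (sym, budget)
        if key in memo:
            return memo[key]
        if g.is_terminal(sym):
            result = frozenset([(sym,)]) if budget >= 1 else frozenset()
        else:
            acc: set[tuple[str, ...]] = set()
            for p in g.productions_for(sym):
                if 1 + max(g.min_height(s) for s in p.rhs) > budget:
                    continue
                parts = [sentences(s, budget - 1) for s in p.rhs]
                combos = 1
                for part in parts:
                    combos *= len(part)
                if combos + len(acc) > cap:
                    raise EnumerationCapError(
                        f"enumeration at depth {budget} for {sym!r} exceeds cap {cap}"
                    )
                for combo in itertools.product(*parts):
                    acc.add(tuple(itertools.chain.from_iterable(combo)))
                if len(acc) > cap:
                    raise EnumerationCapError(
                        f"enumeration at depth {budget} exceeds cap {cap}"
                    )
            result = frozenset(acc)
        memo[key] = result
        return result

    roots = [symbol] if symbol is not None else sorted(g.start)
    out: set[tuple[str, ...]] = set()
    for root in roots:
        out |= sentences(root, max_depth)
    return out
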