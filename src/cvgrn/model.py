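"""Complex-valued ODE models for single-gene dynamics.

One target gene i is modeled as

    dZ_i/dt = sum_k  beta_k * e_k(Z)

where the beta_k are complex coefficients and each e_k is an algebraic
expression over the complex gene states, decoded from a derivation tree of
the expression grammar.  Evaluation uses complex sin/cos/arithmetic with
protected division; integration is classic fixed-step RK4 in which the
non-target genes are supplied by linear interpolation of the observed data
("decoupled" integration).
"""

from __future__ import annotations

import cmath
import re
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence, Union

import numpy as np

from .grammar import DerivationTree

__all__ = [
    "Var",
    "Unary",
    "Binary",
    "Expression",
    "ModelError",
    "DivergenceError",
    "protected_div",
    "expr_variables",
    "expr_to_infix",
    "expr_to_dict",
    "expr_from_dict",
    "CVODETerm",
    "CVODEModel",
    "CVODESystem",
    "terms_from_tree",
    "from_derivation",
    "extract_regulators",
    "CompiledStructure",
    "integrate_decoupled",
    "integrate_structure_batch",
]

#: protected-division threshold on |denominator|
DIV_EPS = 1e-6
#: |Z| beyond which an integration is declared divergent
DIVERGENCE_BOUND = 1e6
#: fitness assigned to divergent / non-finite candidate models
PENALTY_FITNESS = 1e9


class ModelError(ValueError):
    """Malformed model or model operation."""


class DivergenceError(RuntimeError):
    """Trajectory magnitude exceeded the divergence bound."""


# ---------------------------------------------------------------------------
# Expression AST
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Var:
    """Gene variable x_index (1-based)."""

    index: int


@dataclass(frozen=True)
class Unary:
    fn: str  # 'sin' | 'cos'
    child: "Expression"


@dataclass(frozen=True)
class Binary:
    op: str  # '+' | '-' | '*' | '/'
    left: "Expression"
    right: "Expression"


Expression = Union[Var, Unary, Binary]

_UNARY_FNS_SCALAR = {"sin": cmath.sin, "cos": cmath.cos}
_UNARY_FNS_BATCH = {"sin": np.sin, "cos": np.cos}


def protected_div(a: complex, b: complex, eps: float = DIV_EPS) -> complex:
    """a/b with small-denominator protection.

    If |b| >= eps this is plain division; otherwise the denominator is
    replaced by eps * (b/|b|) (or eps when b is exactly zero), so the result
    stays finite while keeping the denominator's phase.
    """
    if eps <= 0:
        raise ModelError("eps must be positive")
    mag = abs(b)
    if mag >= eps:
        return a / b
    if mag == 0:
        return a / eps
    return a / (eps * (b / mag))


def _protected_div_batch(a: np.ndarray, b: np.ndarray, eps: float = DIV_EPS) -> np.ndarray:
    mag = np.abs(b)
    small = mag < eps
    unit = np.where(mag == 0, 1.0 + 0j, b / np.where(mag == 0, 1.0, mag))
    denom = np.where(small, eps * unit, b)
    return a / denom


def expr_variables(e: Expression) -> frozenset[int]:
    """All gene indices referenced anywhere in the expression."""
    if isinstance(e, Var):
        return frozenset([e.index])
    if isinstance(e, Unary):
        return expr_variables(e.child)
    return expr_variables(e.left) | expr_variables(e.right)


def expr_to_infix(e: Expression, names: Sequence[str] | None = None) -> str:
    if isinstance(e, Var):
        return names[e.index - 1] if names else f"x_{e.index}"
    if isinstance(e, Unary):
        return f"{e.fn}({expr_to_infix(e.child, names)})"
    return f"({expr_to_infix(e.left, names)} {e.op} {expr_to_infix(e.right, names)})"


def expr_to_dict(e: Expression) -> dict:
    if isinstance(e, Var):
        return {"kind": "var", "index": e.index}
    if isinstance(e, Unary):
        return {"kind": "unary", "fn": e.fn, "child": expr_to_dict(e.child)}
    return {
        "kind": "binary",
        "op": e.op,
        "left": expr_to_dict(e.left),
        "right": expr_to_dict(e.right),
    }


def expr_from_dict(d: Mapping) -> Expression:
    kind = d["kind"]
    if kind == "var":
        return Var(int(d["index"]))
    if kind == "unary":
        return Unary(d["fn"], expr_from_dict(d["child"]))
    if kind == "binary":
        return Binary(d["op"], expr_from_dict(d["left"]), expr_from_dict(d["right"]))
    raise ModelError(f"unknown expression kind {kind!r}")


def compile_scalar(e: Expression) -> Callable[[Sequence[complex]], complex]:
    """Compile to a closure evaluating on a length-m complex state vector."""
    if isinstance(e, Var):
        i = e.index - 1
        return lambda z: z[i]
    if isinstance(e, Unary):
        f = _UNARY_FNS_SCALAR[e.fn]
        c = compile_scalar(e.child)
        return lambda z: f(c(z))
    left = compile_scalar(e.left)
    right = compile_scalar(e.right)
    if e.op == "+":
        return lambda z: left(z) + right(z)
    if e.op == "-":
        return lambda z: left(z) - right(z)
    if e.op == "*":
        return lambda z: left(z) * right(z)
    if e.op == "/":
        return lambda z: protected_div(left(z), right(z))
    raise ModelError(f"unknown operator {e.op!r}")


def compile_batch(e: Expression) -> Callable[[np.ndarray], np.ndarray]:
    """Compile to a closure evaluating on an (m, B) complex state array."""
    if isinstance(e, Var):
        i = e.index - 1
        return lambda Z: Z[i]
    if isinstance(e, Unary):
        f = _UNARY_FNS_BATCH[e.fn]
        c = compile_batch(e.child)
        return lambda Z: f(c(Z))
    left = compile_batch(e.left)
    right = compile_batch(e.right)
    if e.op == "+":
        return lambda Z: left(Z) + right(Z)
    if e.op == "-":
        return lambda Z: left(Z) - right(Z)
    if e.op == "*":
        return lambda Z: left(Z) * right(Z)
    if e.op == "/":
        return lambda Z: _protected_div_batch(left(Z), right(Z))
    raise ModelError(f"unknown operator {e.op!r}")


# ---------------------------------------------------------------------------
# Genotype -> phenotype decoding
# ---------------------------------------------------------------------------

_VAR_RE = re.compile(r"^x_(\d+)$")


def _var_index(name: str, var_index: Mapping[str, int] | None) -> int:
    if var_index is not None and name in var_index:
        return var_index[name]
    m = _VAR_RE.match(name)
    if not m:
        raise ModelError(f"cannot map variable terminal {name!r} to a gene index")
    return int(m.group(1))


def _expr_root(tree: DerivationTree) -> DerivationTree:
    node = tree
    while node.symbol == "s":
        node = node.children[0]
    return node


def _to_expression(node: DerivationTree, var_index: Mapping[str, int] | None) -> Expression:
    syms = tuple(c.symbol for c in node.children)
    if syms == ("var",):
        return Var(_var_index(node.children[0].children[0].symbol, var_index))
    if syms == ("pre", "expr"):
        fn = node.children[0].children[0].symbol
        return Unary(fn, _to_expression(node.children[1], var_index))
    if syms == ("expr", "op", "expr"):
        op = node.children[1].children[0].symbol
        return Binary(
            op,
            _to_expression(node.children[0], var_index),
            _to_expression(node.children[2], var_index),
        )
    raise ModelError(f"unrecognized expr node with children {syms}")


def terms_from_tree(
    tree: DerivationTree, var_index: Mapping[str, int] | None = None
) -> list[tuple[int, Expression]]:
    """Split a derivation tree into its top-level signed additive terms.

    The outermost chain of +/- operators is flattened; '-' flips the sign of
    everything to its right operand.  Each term is returned as
    (sign, expression); multiplicative and nested structure is untouched.
    """
    root = _expr_root(tree)

    def split(node: DerivationTree, sign: int) -> list[tuple[int, Expression]]:
        syms = tuple(c.symbol for c in node.children)
        if syms == ("expr", "op", "expr"):
            op = node.children[1].children[0].symbol
            if op in "+-":
                right_sign = sign if op == "+" else -sign
                return split(node.children[0], sign) + split(
                    node.children[2], right_sign
                )
        return [(sign, _to_expression(node, var_index))]

    return split(root, 1)


# ---------------------------------------------------------------------------
# Model types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CVODETerm:
    """One additive term: sign * coefficient * expression."""

    coefficient: complex
    expr: Expression
    sign: int = 1


class CVODEModel:
    """dZ_target/dt = sum_k sign_k * beta_k * e_k(Z)."""

    def __init__(self, target: int, terms: Iterable[CVODETerm], n_genes: int | None = None):
        self.target = int(target)
        self.terms = tuple(terms)
        if not self.terms:
            raise ModelError("a model needs at least one term")
        for t in self.terms:
            c = complex(t.coefficient)
            if not (np.isfinite(c.real) and np.isfinite(c.imag)):
                raise ModelError("coefficients must be finite")
        self.n_genes = n_genes
        refs = self.regulators()
        if n_genes is not None and refs and max(refs) > n_genes:
            raise ModelError(
                f"model references gene {max(refs)} but only {n_genes} genes exist"
            )
        self._compiled: list[Callable] | None = None

    def regulators(self) -> frozenset[int]:
        out: frozenset[int] = frozenset()
        for t in self.terms:
            out |= expr_variables(t.expr)
        return out

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([t.coefficient for t in self.terms], dtype=complex)

    def _fns(self) -> list[Callable]:
        if self._compiled is None:
            self._compiled = [compile_scalar(t.expr) for t in self.terms]
        return self._compiled

    def evaluate(self, state: Sequence[complex]) -> complex:
        """RHS value at a complex state vector (length >= max referenced index)."""
        arr = np.asarray(state, dtype=complex)
        if np.any(np.isnan(arr)):
            raise ModelError("NaN in state vector")
        total = 0j
        for t, f in zip(self.terms, self._fns()):
            total += t.sign * complex(t.coefficient) * f(arr)
        return total

    def to_infix(self, names: Sequence[str] | None = None) -> str:
        parts = []
        for t in self.terms:
            c = complex(t.coefficient)
            sign = "-" if t.sign < 0 else "+"
            parts.append(
                f"{sign} ({c.real:.6g}{c.imag:+.6g}i)*{expr_to_infix(t.expr, names)}"
            )
        s = " ".join(parts)
        return s[2:] if s.startswith("+ ") else s

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "terms": [
                {
                    "sign": t.sign,
                    "coefficient": [complex(t.coefficient).real, complex(t.coefficient).imag],
                    "expr": expr_to_dict(t.expr),
                    "infix": expr_to_infix(t.expr),
                }
                for t in self.terms
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping, n_genes: int | None = None) -> "CVODEModel":
        terms = [
            CVODETerm(
                complex(t["coefficient"][0], t["coefficient"][1]),
                expr_from_dict(t["expr"]),
                int(t.get("sign", 1)),
            )
            for t in d["terms"]
        ]
        return cls(int(d["target"]), terms, n_genes=n_genes)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CVODEModel(dZ_{self.target}/dt = {self.to_infix()})"


@dataclass
class CVODESystem:
    """One model per gene, model k targeting gene k."""

    models: list[CVODEModel]

    def __post_init__(self) -> None:
        for k, mod in enumerate(self.models, 1):
            if mod.target != k:
                raise ModelError(f"model at slot {k} targets gene {mod.target}")

    @property
    def m(self) -> int:
        return len(self.models)


def from_derivation(
    tree: DerivationTree,
    coefficients: Sequence[complex],
    target: int = 1,
    var_index: Mapping[str, int] | None = None,
    n_genes: int | None = None,
) -> CVODEModel:
    """Decode a derivation tree plus coefficient vector into a model.

    The coefficient vector must have exactly one entry per top-level
    additive term of the tree.
    """
    signed = terms_from_tree(tree, var_index)
    coeffs = list(coefficients)
    if len(coeffs) != len(signed):
        raise ModelError(
            f"coefficient vector length {len(coeffs)} != term count {len(signed)}"
        )
    terms = [CVODETerm(complex(c), e, s) for c, (s, e) in zip(coeffs, signed)]
    return CVODEModel(target, terms, n_genes=n_genes)


def extract_regulators(model: CVODEModel) -> frozenset[int]:
    """Gene indices whose variables appear anywhere in the model."""
    return model.regulators()


# ---------------------------------------------------------------------------
# Compiled structure (shared by fitness evaluation and CFA refitting)
# ---------------------------------------------------------------------------


class CompiledStructure:
    """A fixed model structure with fast scalar and batch RHS evaluation.

    Decouples the derivation tree (or explicit term list) from its
    coefficients so that the firefly optimizer can sweep coefficient vectors
    without re-decoding the tree.
    """

    def __init__(
        self,
        source: DerivationTree | Sequence[CVODETerm],
        var_index: Mapping[str, int] | None = None,
    ) -> None:
        if isinstance(source, DerivationTree):
            signed = terms_from_tree(source, var_index)
            self.signs = np.array([s for s, _ in signed], dtype=float)
            self.exprs = [e for _, e in signed]
        else:
            terms = list(source)
            self.signs = np.array([t.sign for t in terms], dtype=float)
            self.exprs = [t.expr for t in terms]
        self.n_terms = len(self.exprs)
        self._scalar = [compile_scalar(e) for e in self.exprs]
        self._batch = [compile_batch(e) for e in self.exprs]
        self.variables: frozenset[int] = frozenset().union(
            *[expr_variables(e) for e in self.exprs]
        )

    def rhs_scalar(self, coeffs: np.ndarray, z: np.ndarray) -> complex:
        total = 0j
        for k, f in enumerate(self._scalar):
            total += self.signs[k] * coeffs[k] * f(z)
        return total

    def rhs_batch(self, coeffs: np.ndarray, Z: np.ndarray) -> np.ndarray:
        """coeffs: (K, B); Z: (m, B) -> (B,)."""
        total = np.zeros(Z.shape[1], dtype=complex)
        for k, f in enumerate(self._batch):
            total += self.signs[k] * coeffs[k] * f(Z)
        return total

    def term_values(self, Z: np.ndarray) -> np.ndarray:
        """Signed term values e_k on an (m, B) state array -> (K, B)."""
        return np.stack([self.signs[k] * f(Z) for k, f in enumerate(self._batch)])

    def model(self, coefficients: Sequence[complex], target: int) -> CVODEModel:
        terms = [
            CVODETerm(complex(c), e, int(s))
            for c, e, s in zip(coefficients, self.exprs, self.signs)
        ]
        return CVODEModel(target, terms)


# ---------------------------------------------------------------------------
# Decoupled RK4 integration
# ---------------------------------------------------------------------------


def _stage_grid(data, start: int, stop: int, substeps: int) -> np.ndarray:
    """Linear interpolation of all genes on the half-substep grid.

    Returns an array of shape (stop-start, 2*substeps+1, m): for each sample
    interval, the interpolated complex state at t + j*h/2 for j = 0..2s.
    Cached on the data object (keyed by the range) because it is identical
    for every candidate model.
    """
    cache = getattr(data, "_stage_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(data, "_stage_cache", cache)
    key = (start, stop, substeps)
    if key in cache:
        return cache[key]
    times = np.asarray(data.times, dtype=float)
    values = np.asarray(data.values)
    if np.any(np.diff(times) <= 0):
        raise ModelError("time grid must be strictly increasing")
    n_int = stop - start
    m = values.shape[0]
    grid = np.empty((n_int, 2 * substeps + 1, m), dtype=complex)
    frac = np.arange(2 * substeps + 1) / (2 * substeps)
    for k in range(n_int):
        a = values[:, start + k]
        b = values[:, start + k + 1]
        grid[k] = a[None, :] + frac[:, None] * (b - a)[None, :]
    cache[key] = grid
    return grid


def integrate_decoupled(
    model: CVODEModel,
    data,
    start: int = 0,
    stop: int | None = None,
    substeps: int = 4,
) -> np.ndarray:
    """RK4 trajectory of the target gene over sample indices [start, stop].

    The initial value is the observed complex value of the target gene at
    ``start``; non-target genes are linearly interpolated from ``data`` at
    intermediate RK4 stage times.  Raises DivergenceError if |Z| exceeds
    the divergence bound.
    """
    structure = CompiledStructure(model.terms)
    coeffs = model.coefficients
    traj, diverged = integrate_structure_batch(
        structure, coeffs[:, None], model.target, data, start, stop, substeps
    )
    if diverged[0]:
        raise DivergenceError(
            f"|Z_{model.target}| exceeded {DIVERGENCE_BOUND:g} during integration"
        )
    return traj[:, 0]


def _stage_grid_lists(data, start: int, stop: int, substeps: int) -> list:
    """The _stage_grid interpolation as nested Python lists (fast scalar path)."""
    cache = getattr(data, "_stage_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(data, "_stage_cache", cache)
    key = ("lists", start, stop, substeps)
    if key in cache:
        return cache[key]
    grid = _stage_grid(data, start, stop, substeps)
    lists = [[list(stage) for stage in interval] for interval in grid]
    cache[key] = lists
    return lists


def integrate_structure_scalar(
    structure: CompiledStructure,
    coeffs: np.ndarray,
    target: int,
    data,
    start: int = 0,
    stop: int | None = None,
    substeps: int = 4,
) -> tuple[np.ndarray, bool]:
    """Decoupled RK4 for a single coefficient vector, in scalar arithmetic.

    Same contract as integrate_structure_batch with B = 1, but evaluated
    with Python complex scalars — the per-candidate workhorse of the
    genetic search, where numpy's per-call overhead on length-1 arrays
    dominates.  Returns (trajectory (T,), diverged flag).
    """
    times = np.asarray(data.times, dtype=float)
    n = times.shape[0]
    if stop is None:
        stop = n - 1
    if not (0 <= start < stop <= n - 1):
        raise ModelError(f"invalid index range [{start}, {stop}] for {n} samples")
    if substeps < 1:
        raise ModelError("substeps must be >= 1")
    grid = _stage_grid_lists(data, start, stop, substeps)
    fns = structure._scalar
    cs = [complex(s * c) for s, c in zip(structure.signs, coeffs)]

    def rhs(z: list) -> complex:
        total = 0j
        for c, f in zip(cs, fns):
            total += c * f(z)
        return total

    i = target - 1
    y = complex(data.values[i, start])
    traj = np.empty(stop - start + 1, dtype=complex)
    traj[0] = y
    for k in range(stop - start):
        h = (times[start + k + 1] - times[start + k]) / substeps
        base = grid[k]
        for s in range(substeps):
            j0 = 2 * s
            try:
                z = base[j0].copy()
                z[i] = y
                k1 = rhs(z)
                zm = base[j0 + 1].copy()
                zm[i] = y + 0.5 * h * k1
                k2 = rhs(zm)
                zm[i] = y + 0.5 * h * k2
                k3 = rhs(zm)
                z2 = base[j0 + 2].copy()
                z2[i] = y + h * k3
                k4 = rhs(z2)
                y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            except (OverflowError, ValueError):
                traj[k + 1 :] = 0j
                return traj, True
            if abs(y) > DIVERGENCE_BOUND or y != y:
                traj[k + 1 :] = 0j
                return traj, True
        traj[k + 1] = y
    return traj, False


def integrate_structure_batch(
    structure: CompiledStructure,
    coeffs: np.ndarray,
    target: int,
    data,
    start: int = 0,
    stop: int | None = None,
    substeps: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Decoupled RK4 for B coefficient vectors at once.

    coeffs has shape (K, B).  Returns (trajectory (T, B), diverged (B,));
    diverged candidates are frozen at 0 once they pass the bound.
    """
    times = np.asarray(data.times, dtype=float)
    n = times.shape[0]
    if stop is None:
        stop = n - 1
    if not (0 <= start < stop <= n - 1):
        raise ModelError(f"invalid index range [{start}, {stop}] for {n} samples")
    if substeps < 1:
        raise ModelError("substeps must be >= 1")
    grid = _stage_grid(data, start, stop, substeps)
    i = target - 1
    B = coeffs.shape[1]
    y = np.full(B, data.values[i, start], dtype=complex)
    diverged = np.zeros(B, dtype=bool)
    traj = np.empty((stop - start + 1, B), dtype=complex)
    traj[0] = y
    rhs = structure.rhs_batch
    with np.errstate(all="ignore"):
        for k in range(stop - start):
            h = (times[start + k + 1] - times[start + k]) / substeps
            base = grid[k]
            for s in range(substeps):
                j0 = 2 * s
                Z = np.repeat(base[j0][:, None], B, axis=1)
                Z[i] = y
                k1 = rhs(coeffs, Z)
                Zm = np.repeat(base[j0 + 1][:, None], B, axis=1)
                Zm[i] = y + 0.5 * h * k1
                k2 = rhs(coeffs, Zm)
                Zm[i] = y + 0.5 * h * k2
                k3 = rhs(coeffs, Zm)
                Z2 = np.repeat(base[j0 + 2][:, None], B, axis=1)
                Z2[i] = y + h * k3
                k4 = rhs(coeffs, Z2)
                y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                bad = ~np.isfinite(y.real) | ~np.isfinite(y.imag) | (
                    np.abs(y) > DIVERGENCE_BOUND
                )
                if bad.any():
                    diverged |= bad
                    y = np.where(diverged, 0j, y)
            traj[k + 1] = np.where(diverged, 0j, y)
    return traj, diverged
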