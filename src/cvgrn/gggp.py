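"""Grammar-guided genetic programming over derivation trees.

Each individual is a derivation tree (model structure) plus one complex
coefficient per top-level additive term.  Fitness is the training-window
prediction RMSE: the candidate model is integrated (decoupled RK4) from the
first training point and its back-converted real trajectory is compared
with the observed series of the target gene.  Divergent or non-finite
candidates receive a large penalty instead of being rejected, keeping the
population size constant.

Coefficients of structurally new individuals are initialized by a complex
least-squares fit of finite-difference expression slopes onto the term
values (the classic two-step / gradient-matching surrogate); every
``cfa_every`` generations, and at the end, the complex-valued firefly
algorithm refines the best individual's coefficients with the structure
held fixed, keeping the refit only if it improves.

Selection adds a small parsimony penalty (per tree node) to the RMSE so
that terms whose only contribution is riding below the integration
residual do not accumulate; reported fitness is always the pure RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ComplexMatrix, complex_to_real_values
from .firefly import CFAParams, cfa_optimize
from .grammar import DerivationTree, Grammar, random_derivation
from .model import (
    PENALTY_FITNESS,
    CompiledStructure,
    integrate_structure_batch,
    integrate_structure_scalar,
)

__all__ = [
    "GGGPParams",
    "Individual",
    "EvolutionResult",
    "crossover",
    "mutate",
    "fitness_of",
    "evolve",
]


@dataclass
class GGGPParams:
    population: int = 50
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    generations: int = 100
    tournament_size: int = 3
    elitism: int = 1
    cfa_every: int = 5  # CFA coefficient refit cadence (generations)
    max_depth_init: int = 6  # depth budget for initial random trees
    max_depth: int = 10  # hard cap after genetic operators
    parsimony: float = 5e-4  # selection penalty per tree node (not in fitness)
    fitness_tol: float = 1e-8  # early stop when best RMSE drops below
    substeps: int = 4  # RK4 substeps per sample interval
    cfa: CFAParams = field(default_factory=CFAParams)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        for name in ("crossover_rate", "mutation_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.tournament_size < 1 or self.elitism < 0:
            raise ValueError("bad tournament/elitism settings")


@dataclass
class Individual:
    tree: DerivationTree
    coefficients: np.ndarray  # complex, one per top-level term
    fitness: float = np.inf  # prediction RMSE (lower is better)

    _structure: CompiledStructure | None = field(default=None, repr=False, compare=False)

    def structure(self) -> CompiledStructure:
        if self._structure is None:
            self._structure = CompiledStructure(self.tree)
        return self._structure


@dataclass
class EvolutionResult:
    best: Individual
    trace: list[float]  # best-ever fitness per generation (gen 0 included)
    generations_run: int


# ---------------------------------------------------------------------------
# Tree surgery
# ---------------------------------------------------------------------------


def _nodes_with_paths(
    t: DerivationTree, path: tuple[int, ...] = ()
) -> list[tuple[tuple[int, ...], DerivationTree]]:
    out = [(path, t)]
    for i, c in enumerate(t.children):
        out.extend(_nodes_with_paths(c, path + (i,)))
    return out


def _subtree_at(t: DerivationTree, path: tuple[int, ...]) -> DerivationTree:
    for i in path:
        t = t.children[i]
    return t


def _replace_at(
    t: DerivationTree, path: tuple[int, ...], sub: DerivationTree
) -> DerivationTree:
    if not path:
        return sub
    i = path[0]
    children = list(t.children)
    children[i] = _replace_at(children[i], path[1:], sub)
    return DerivationTree(t.symbol, tuple(children))


def crossover(
    a: DerivationTree,
    b: DerivationTree,
    rng: np.random.Generator,
    max_depth: int = 10,
    max_tries: int = 10,
) -> tuple[DerivationTree, DerivationTree]:
    """Swap one subtree pair whose roots carry the same nonterminal symbol.

    Candidate crossover points are all internal (nonterminal) nodes except
    the roots.  If no common nonterminal exists, or every sampled swap
    breaks the depth cap, the parents are returned unchanged.
    """
    cand_a = [(p, n) for p, n in _nodes_with_paths(a) if p and not n.is_leaf]
    cand_b = [(p, n) for p, n in _nodes_with_paths(b) if p and not n.is_leaf]
    by_sym_a: dict[str, list[tuple[tuple[int, ...], DerivationTree]]] = {}
    by_sym_b: dict[str, list[tuple[tuple[int, ...], DerivationTree]]] = {}
    for p, n in cand_a:
        by_sym_a.setdefault(n.symbol, []).append((p, n))
    for p, n in cand_b:
        by_sym_b.setdefault(n.symbol, []).append((p, n))
    common = sorted(set(by_sym_a) & set(by_sym_b))
    if not common:
        return a, b
    for _ in range(max_tries):
        sym = common[int(rng.integers(len(common)))]
        pa, na = by_sym_a[sym][int(rng.integers(len(by_sym_a[sym])))]
        pb, nb = by_sym_b[sym][int(rng.integers(len(by_sym_b[sym])))]
        child_a = _replace_at(a, pa, nb)
        child_b = _replace_at(b, pb, na)
        if child_a.depth <= max_depth and child_b.depth <= max_depth:
            return child_a, child_b
    return a, b


def mutate(
    t: DerivationTree,
    g: Grammar,
    rng: np.random.Generator,
    max_depth: int = 10,
) -> DerivationTree:
    """Point mutation: regrow at a nonterminal, or swap a terminal leaf.

    One node is selected uniformly.  A nonterminal node's subtree is
    regrown from that symbol within the depth cap; a terminal leaf is
    replaced by a random terminal admissible in the same production slot.
    """
    nodes = _nodes_with_paths(t)
    path, node = nodes[int(rng.integers(len(nodes)))]
    level = len(path) + 1
    if node.symbol in g.nonterminals:
        budget = max(g.min_height(node.symbol), max_depth - level + 1)
        sub = random_derivation(g, budget, rng, symbol=node.symbol)
        return _replace_at(t, path, sub)
    if not path:  # lone terminal root: nothing sensible to do
        return t
    parent = _subtree_at(t, path[:-1])
    slot = path[-1]
    alts = [
        p.rhs[slot]
        for p in g.productions_for(parent.symbol)
        if len(p.rhs) == len(parent.children)
        and p.rhs[slot] in g.terminals
        and all(
            p.rhs[j] == parent.children[j].symbol
            for j in range(len(p.rhs))
            if j != slot
        )
    ]
    if not alts:
        return t
    new_sym = alts[int(rng.integers(len(alts)))]
    return _replace_at(t, path, DerivationTree(new_sym))


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------


def _observed_real(train: ComplexMatrix, target: int, mode: str) -> np.ndarray:
    return complex_to_real_values(train.values[target - 1], mode)


def _batch_fitness(
    structure: CompiledStructure,
    coeffs: np.ndarray,
    target: int,
    train: ComplexMatrix,
    mode: str,
    substeps: int,
) -> np.ndarray:
    """Training-window prediction RMSE for B coefficient vectors (K, B)."""
    if coeffs.shape[1] == 1:
        t, div = integrate_structure_scalar(
            structure, coeffs[:, 0], target, train, 0, train.n - 1, substeps
        )
        traj, diverged = t[:, None], np.array([div])
    else:
        traj, diverged = integrate_structure_batch(
            structure, coeffs, target, train, 0, train.n - 1, substeps
        )
    pred = complex_to_real_values(traj, mode)  # (T, B)
    obs = _observed_real(train, target, mode)  # (T,)
    with np.errstate(all="ignore"):
        err = np.sqrt(np.mean((pred - obs[:, None]) ** 2, axis=0))
    err = np.where(diverged | ~np.isfinite(err), PENALTY_FITNESS, err)
    return err


def fitness_of(
    ind: Individual,
    target: int,
    train: ComplexMatrix,
    mode: str = "phase45",
    substeps: int = 4,
) -> float:
    """Prediction RMSE of one individual on the training window."""
    if train.n < 2:
        raise ValueError("training window needs at least 2 time points")
    coeffs = np.asarray(ind.coefficients, dtype=complex)[:, None]
    return float(
        _batch_fitness(ind.structure(), coeffs, target, train, mode, substeps)[0]
    )


def _ls_init_coefficients(
    structure: CompiledStructure,
    target: int,
    train: ComplexMatrix,
    rng: np.random.Generator,
    init_radius: float,
) -> np.ndarray:
    """Least-squares coefficient guess from finite-difference slopes.

    Solves min_beta || dZ_i/dt - sum_k beta_k e_k(Z) ||^2 on the training
    samples, with slopes taken as interval differences and term values at
    the interval-midpoint state (second-order accurate pairing).  Falls
    back to a random draw if the system is degenerate.
    """
    K = structure.n_terms
    try:
        dt = np.diff(train.times)
        slopes = np.diff(train.values[target - 1]) / dt  # (n-1,)
        mid = 0.5 * (train.values[:, :-1] + train.values[:, 1:])
        F = structure.term_values(mid)  # (K, n-1)
        if not np.all(np.isfinite(F)):
            raise np.linalg.LinAlgError
        beta, *_ = np.linalg.lstsq(F.T, slopes, rcond=None)
        if not np.all(np.isfinite(beta)):
            raise np.linalg.LinAlgError
        return beta
    except np.linalg.LinAlgError:
        re = init_radius * (2 * rng.random(K) - 1)
        im = init_radius * (2 * rng.random(K) - 1)
        return re + 1j * im


def _new_individual(
    tree: DerivationTree,
    target: int,
    train: ComplexMatrix,
    mode: str,
    params: GGGPParams,
    rng: np.random.Generator,
) -> Individual:
    ind = Individual(tree, np.zeros(1, dtype=complex))
    structure = ind.structure()
    ind.coefficients = _ls_init_coefficients(
        structure, target, train, rng, params.cfa.init_radius
    )
    ind.fitness = float(
        _batch_fitness(
            structure,
            ind.coefficients[:, None],
            target,
            train,
            mode,
            params.substeps,
        )[0]
    )
    return ind


def _refit_with_cfa(
    ind: Individual,
    target: int,
    train: ComplexMatrix,
    mode: str,
    params: GGGPParams,
    rng: np.random.Generator,
) -> Individual:
    """CFA coefficient refit with the structure fixed; keeps the better of
    incumbent and refit (the incumbent is seeded as firefly 0)."""
    structure = ind.structure()

    def batch_obj(C: np.ndarray) -> np.ndarray:
        return _batch_fitness(structure, C, target, train, mode, params.substeps)

    def obj(c: np.ndarray) -> float:
        return float(batch_obj(np.asarray(c, dtype=complex)[:, None])[0])

    res = cfa_optimize(
        obj,
        structure.n_terms,
        params.cfa,
        rng,
        x0=ind.coefficients,
        batch_objective=batch_obj,
    )
    if res.fitness < ind.fitness:
        out = Individual(ind.tree, np.asarray(res.position, dtype=complex), res.fitness)
        out._structure = structure
        return out
    return ind


# ---------------------------------------------------------------------------
# Evolution loop
# ---------------------------------------------------------------------------


def _selection_key(ind: Individual, params: GGGPParams) -> float:
    return ind.fitness + params.parsimony * ind.tree.n_nodes


def _tournament(
    pop: list[Individual], params: GGGPParams, rng: np.random.Generator
) -> Individual:
    idx = rng.integers(len(pop), size=params.tournament_size)
    best = min(sorted(int(i) for i in idx), key=lambda i: (_selection_key(pop[i], params), i))
    return pop[best]


def evolve(
    target: int,
    train: ComplexMatrix,
    grammar: Grammar,
    params: GGGPParams | None = None,
    rng: np.random.Generator | None = None,
    mode: str = "phase45",
) -> EvolutionResult:
    """Search the best model structure + coefficients for one target gene.

    Tournament selection with elitism, subtree crossover and grammar-guided
    mutation; CFA coefficient refits of the running best every
    ``cfa_every`` generations and on the final best.  Deterministic for a
    fixed rng state.  The returned trace holds the best-ever fitness after
    each generation (including generation 0) and is non-increasing.
    """
    params = params or GGGPParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)

    pop = [
        _new_individual(
            random_derivation(grammar, params.max_depth_init, rng),
            target,
            train,
            mode,
            params,
            rng,
        )
        for _ in range(params.population)
    ]
    # best model by the parsimony-adjusted key (what evolve returns) and the
    # best raw RMSE ever seen (what the monotone trace reports)
    best = min(pop, key=lambda d: _selection_key(d, params))
    best_rmse = min(d.fitness for d in pop)
    trace = [best_rmse]
    gens_run = 0

    for gen in range(1, params.generations + 1):
        gens_run = gen
        ranked = sorted(
            range(len(pop)), key=lambda i: (_selection_key(pop[i], params), i)
        )
        newpop = [pop[i] for i in ranked[: params.elitism]]
        while len(newpop) < params.population:
            pa = _tournament(pop, params, rng)
            pb = _tournament(pop, params, rng)
            if rng.random() < params.crossover_rate:
                ta, tb = crossover(pa.tree, pb.tree, rng, params.max_depth)
            else:
                ta, tb = pa.tree, pb.tree
            for tree, parent in ((ta, pa), (tb, pb)):
                if len(newpop) >= params.population:
                    break
                if rng.random() < params.mutation_rate:
                    tree = mutate(tree, grammar, rng, params.max_depth)
                if tree is parent.tree:
                    newpop.append(parent)  # unchanged: keep cached fitness
                else:
                    newpop.append(
                        _new_individual(tree, target, train, mode, params, rng)
                    )
        pop = newpop

        if params.cfa_every > 0 and gen % params.cfa_every == 0:
            ib = min(
                range(len(pop)), key=lambda i: (_selection_key(pop[i], params), i)
            )
            pop[ib] = _refit_with_cfa(pop[ib], target, train, mode, params, rng)

        gen_best = min(pop, key=lambda d: _selection_key(d, params))
        if _selection_key(gen_best, params) < _selection_key(best, params):
            best = gen_best
        best_rmse = min(best_rmse, min(d.fitness for d in pop))
        trace.append(best_rmse)
        if best_rmse < params.fitness_tol:
            break

    best = _refit_with_cfa(best, target, train, mode, params, rng)
    if trace and best.fitness < trace[-1]:
        trace[-1] = best.fitness
    return EvolutionResult(best, trace, gens_run)
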