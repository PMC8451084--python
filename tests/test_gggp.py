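"""Genetic operators, fitness and the evolutionary loop."""

import numpy as np
import pytest

from cvgrn.data import ComplexMatrix, real_to_complex_values
from cvgrn.firefly import CFAParams
from cvgrn.gggp import (
    GGGPParams,
    Individual,
    crossover,
    evolve,
    fitness_of,
    mutate,
)
from cvgrn.grammar import (
    default_grammar,
    random_derivation,
    tree_yield,
    validate_tree,
)
from cvgrn.model import CVODEModel, CVODESystem, CVODETerm, Var
from cvgrn.synthetic import _integrate_coupled

from conftest import e_pre, e_var, s_tree


def small_params(**kw) -> GGGPParams:
    base = dict(
        population=12,
        generations=6,
        cfa_every=3,
        cfa=CFAParams(population=15, iterations=10),
    )
    base.update(kw)
    return GGGPParams(**base)


@pytest.fixture(scope="module")
def self_decay_data():
    """Single-gene exponential decay dZ/dt = -0.5 Z, sampled exactly."""
    system = CVODESystem([CVODEModel(1, [CVODETerm(-0.5 + 0j, Var(1), 1)])])
    traj = _integrate_coupled(system, np.array([0.9 + 0j]), 30, 0.2)
    return ComplexMatrix(["G1"], 0.2 * np.arange(30), traj)


class TestCrossover:
    def test_identical_parents_give_valid_yield_equal_children(self, rng):
        g = default_grammar(2)
        t = random_derivation(g, 6, rng)
        ca, cb = crossover(t, t, rng)
        assert validate_tree(g, ca) and validate_tree(g, cb)

    def test_closure_over_many_operations(self, rng):
        g = default_grammar(3)
        pool = [random_derivation(g, 7, rng) for _ in range(40)]
        for _ in range(1000):
            i, j = rng.integers(len(pool), size=2)
            ca, cb = crossover(pool[int(i)], pool[int(j)], rng, max_depth=10)
            assert validate_tree(g, ca) and validate_tree(g, cb)
            assert ca.depth <= 10 and cb.depth <= 10

    def test_var_swap_between_unary_parents_occurs(self, rng):
        g = default_grammar(2)
        a = s_tree(e_pre("sin", e_var("x_1")))
        b = s_tree(e_pre("cos", e_var("x_2")))
        seen = set()
        for _ in range(300):
            ca, cb = crossover(a, b, rng)
            assert validate_tree(g, ca) and validate_tree(g, cb)
            seen.add((" ".join(tree_yield(ca)), " ".join(tree_yield(cb))))
        assert ("sin x_2", "cos x_1") in seen

    def test_no_common_nonterminal_returns_parents(self, rng):
        # minimal trees share only var below the root-excluded region? they
        # share expr/var, so craft bare-leaf parents instead
        a = s_tree(e_var("x_1"))
        ca, cb = crossover(a, a, rng)
        assert validate_tree(default_grammar(1), ca)


class TestMutate:
    def test_minimal_tree_stays_single_variable_under_tight_cap(self, rng):
        g = default_grammar(2)
        t = s_tree(e_var("x_1"))
        seen = set()
        for _ in range(200):
            out = mutate(t, g, rng, max_depth=4)
            assert validate_tree(g, out)
            seen.add(" ".join(tree_yield(out)))
        assert seen <= {"x_1", "x_2"}
        assert seen == {"x_1", "x_2"}  # both reachable

    def test_closure_and_depth_cap(self, rng):
        g = default_grammar(2)
        t = random_derivation(g, 8, rng)
        for _ in range(1000):
            t2 = mutate(t, g, rng, max_depth=10)
            assert validate_tree(g, t2)
            assert t2.depth <= 10


class TestFitness:
    def test_true_model_fits_its_own_data(self, self_decay_data):
        ind = Individual(s_tree(e_var("x_1")), np.array([-0.5 + 0j]))
        fit = fitness_of(ind, 1, self_decay_data, mode="embed")
        assert fit < 1e-10

    def test_zero_coefficients_match_constant_predictor_formula(self, self_decay_data):
        ind = Individual(s_tree(e_var("x_1")), np.array([0j]))
        fit = fitness_of(ind, 1, self_decay_data, mode="embed")
        obs = real_to_complex_values(0, "embed")  # noqa: F841 - clarity only
        series = self_decay_data.values[0].real
        expected = np.sqrt(np.mean((series - series[0]) ** 2))
        assert fit == pytest.approx(expected, rel=1e-12)

    def test_invariant_to_relabeling_of_unused_genes(self, rng):
        times = 0.2 * np.arange(15)
        g1 = np.linspace(0.9, 0.3, 15)
        g2 = rng.random(15)
        g3 = rng.random(15)
        d_23 = ComplexMatrix(["a", "b", "c"], times, np.vstack([g1, g2, g3]).astype(complex))
        d_32 = ComplexMatrix(["a", "c", "b"], times, np.vstack([g1, g3, g2]).astype(complex))
        ind2 = Individual(s_tree(e_var("x_2")), np.array([0.4 + 0.1j]))
        ind3 = Individual(s_tree(e_var("x_3")), np.array([0.4 + 0.1j]))
        assert fitness_of(ind2, 1, d_23, "embed") == pytest.approx(
            fitness_of(ind3, 1, d_32, "embed"), rel=1e-12
        )


class TestEvolve:
    def test_zero_generations_returns_initial_best(self, self_decay_data):
        g = default_grammar(1)
        res = evolve(
            1,
            self_decay_data,
            g,
            small_params(generations=0),
            np.random.default_rng(0),
            mode="embed",
        )
        assert len(res.trace) == 1
        assert np.isfinite(res.best.fitness)

    def test_trace_contract(self, self_decay_data):
        g = default_grammar(1)
        params = small_params(generations=5, fitness_tol=0.0)  # disable early stop
        res = evolve(1, self_decay_data, g, params, np.random.default_rng(1), mode="embed")
        assert len(res.trace) == 6
        assert all(a >= b for a, b in zip(res.trace, res.trace[1:]))

    def test_deterministic_under_fixed_seed(self, self_decay_data):
        g = default_grammar(1)
        runs = [
            evolve(1, self_decay_data, g, small_params(), np.random.default_rng(4), mode="embed")
            for _ in range(2)
        ]
        assert runs[0].trace == runs[1].trace
        assert np.array_equal(runs[0].best.coefficients, runs[1].best.coefficients)
        assert runs[0].best.tree == runs[1].best.tree

    def test_recovers_single_gene_decay(self, self_decay_data):
        """The search should land on the self-regulation structure with a
        coefficient close to the generating -0.5."""
        g = default_grammar(1)
        res = evolve(1, self_decay_data, g, small_params(generations=10),
                     np.random.default_rng(2), mode="embed")
        assert res.best.fitness < 1e-3
        assert res.best.structure().variables == {1}
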