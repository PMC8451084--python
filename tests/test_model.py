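"""Model decoding, complex evaluation, protected division and RK4 integration."""

import cmath

import numpy as np
import pytest

from cvgrn.data import ComplexMatrix
from cvgrn.grammar import default_grammar, random_derivation, tree_yield
from cvgrn.model import (
    Binary,
    CVODEModel,
    CVODESystem,
    CVODETerm,
    DivergenceError,
    ModelError,
    Unary,
    Var,
    extract_regulators,
    from_derivation,
    integrate_decoupled,
    protected_div,
    terms_from_tree,
)

from conftest import e_bin, e_pre, e_var, s_tree, sin_plus_cos_minus


def sos_polB_model() -> CVODEModel:
    """The published polB equation: dx6/dt = (0.0461+0.0237i) x3 x2 - (0.2843+0.0345i) x6^3."""
    x6cubed = Binary("*", Binary("*", Var(6), Var(6)), Var(6))
    return CVODEModel(
        6,
        [
            CVODETerm(0.0461 + 0.0237j, Binary("*", Var(3), Var(2)), 1),
            CVODETerm(0.2843 + 0.0345j, x6cubed, -1),
        ],
    )


class TestProtectedDiv:
    def test_plain_division(self):
        assert protected_div(1 + 0j, 2 + 0j) == 0.5 + 0j

    def test_zero_denominator_uses_eps(self):
        assert protected_div(1 + 0j, 0j) == 1 / 1e-6

    def test_small_denominator_keeps_phase(self):
        out = protected_div(1 + 0j, 1e-9j)
        assert abs(abs(out) - 1 / 1e-6) < 1e-6
        assert abs(np.angle(out) + np.pi / 2) < 1e-12

    def test_continuity_across_threshold(self):
        above = protected_div(1 + 0j, 1.01e-6 + 0j)
        below = protected_div(1 + 0j, 0.99e-6 + 0j)
        assert 0.8 < abs(above) / abs(below) < 1.25


class TestDecoding:
    def test_single_variable_tree(self):
        model = from_derivation(s_tree(e_var("x_1")), [1 + 0j])
        assert len(model.terms) == 1
        assert extract_regulators(model) == {1}

    def test_three_term_split(self):
        model = from_derivation(sin_plus_cos_minus("x_1"), [1, 1, 1])
        assert len(model.terms) == 3
        assert [t.sign for t in model.terms] == [1, 1, -1]

    def test_coefficient_length_mismatch(self):
        with pytest.raises(ModelError, match="length"):
            from_derivation(sin_plus_cos_minus("x_1"), [1, 1])

    def test_nested_minus_is_not_split(self):
        # sin(x_1 - x_2): the '-' sits below the unary, so one term only
        tree = s_tree(e_pre("sin", e_bin(e_var("x_1"), "-", e_var("x_2"))))
        assert len(terms_from_tree(tree)) == 1

    def test_term_count_matches_spine_oracle(self, rng):
        """Independent splitter: walk the additive spine of the raw tree."""

        def spine_terms(node):
            if node.symbol == "s":
                return spine_terms(node.children[0])
            syms = tuple(c.symbol for c in node.children)
            if syms == ("expr", "op", "expr"):
                op = node.children[1].children[0].symbol
                if op in "+-":
                    return spine_terms(node.children[0]) + spine_terms(node.children[2])
            return 1

        g = default_grammar(2)
        for _ in range(200):
            t = random_derivation(g, 8, rng)
            assert len(terms_from_tree(t)) == spine_terms(t)


class TestEvaluate:
    def test_worked_example_at_origin(self):
        model = from_derivation(sin_plus_cos_minus("x_1"), [1, 1, 1])
        assert model.evaluate([0j]) == pytest.approx(1 + 0j)  # sin0 + cos0 - 0

    def test_published_polB_equation_at_ones(self):
        # (0.0461+0.0237i) - (0.2843+0.0345i)
        val = sos_polB_model().evaluate(np.ones(6, dtype=complex))
        assert val == pytest.approx(-0.2382 - 0.0108j, abs=1e-12)

    def test_zero_coefficients_zero_everywhere(self, rng):
        model = from_derivation(sin_plus_cos_minus("x_1"), [0, 0, 0])
        for _ in range(10):
            state = rng.standard_normal(1) + 1j * rng.standard_normal(1)
            assert model.evaluate(state) == 0j

    def test_linearity_in_coefficients(self, rng):
        tree = sin_plus_cos_minus("x_1")
        b1 = rng.standard_normal(3) + 1j * rng.standard_normal(3)
        b2 = rng.standard_normal(3) + 1j * rng.standard_normal(3)
        state = rng.standard_normal(1) + 1j * rng.standard_normal(1)
        lhs = from_derivation(tree, b1 + b2).evaluate(state)
        rhs = from_derivation(tree, b1).evaluate(state) + from_derivation(
            tree, b2
        ).evaluate(state)
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_nan_state_rejected(self):
        model = from_derivation(s_tree(e_var("x_1")), [1])
        with pytest.raises(ModelError, match="NaN"):
            model.evaluate([complex("nan")])

    def test_nonfinite_coefficient_rejected(self):
        with pytest.raises(ModelError, match="finite"):
            CVODEModel(1, [CVODETerm(complex("inf"), Var(1), 1)])


class TestExtractRegulators:
    def test_published_polB_regulators(self):
        assert sorted(extract_regulators(sos_polB_model())) == [2, 3, 6]

    def test_matches_leaf_scan_oracle(self, rng):
        g = default_grammar(3)
        for _ in range(100):
            t = random_derivation(g, 7, rng)
            model = from_derivation(t, np.ones(len(terms_from_tree(t))))
            from_yield = {
                int(tok.split("_")[1]) for tok in tree_yield(t) if tok.startswith("x_")
            }
            assert extract_regulators(model) == from_yield


class TestIntegration:
    def test_zero_model_constant_trajectory(self):
        data = ComplexMatrix(["G1"], np.arange(5.0), np.full((1, 5), 0.7 + 0.2j))
        model = CVODEModel(1, [CVODETerm(0j, Var(1), 1)])
        traj = integrate_decoupled(model, data)
        assert np.allclose(traj, 0.7 + 0.2j)

    def test_rotation_reaches_minus_one(self):
        """dZ/dt = iZ from 1 to t=pi lands on e^{i pi} = -1."""
        data = ComplexMatrix(["G1"], [0.0, np.pi], [[1 + 0j, 0j]])
        model = CVODEModel(1, [CVODETerm(1j, Var(1), 1)])
        traj = integrate_decoupled(model, data, substeps=1000)
        assert abs(traj[-1] - (-1 + 0j)) < 1e-6

    def test_fourth_order_convergence(self):
        """Halving the step shrinks the error vs a fine-Euler oracle ~16x."""
        beta = 0.3 - 0.4j
        T = 2.0
        data = ComplexMatrix(["G1"], [0.0, T], [[0.8 + 0j, 0j]])
        model = CVODEModel(1, [CVODETerm(beta, Unary("sin", Var(1)), 1)])

        # independent very-fine-step Euler oracle; RK4 is compared at coarse
        # steps so its own error dominates the oracle's O(h) bias
        z, n_fine = 0.8 + 0j, 400_000
        h = T / n_fine
        for _ in range(n_fine):
            z = z + h * beta * cmath.sin(z)
        errs = []
        for substeps in (1, 2, 4):
            traj = integrate_decoupled(model, data, substeps=substeps)
            errs.append(abs(traj[-1] - z))
        assert 6 < errs[0] / errs[1] < 40
        assert 6 < errs[1] / errs[2] < 40

    def test_real_system_stays_real(self):
        """With real coefficients and real data the complex model reduces to
        the ordinary real ODE: the trajectory's imaginary part vanishes."""
        times = 0.1 * np.arange(10)
        vals = np.vstack([np.linspace(0.2, 0.9, 10), np.linspace(0.8, 0.1, 10)]).astype(
            complex
        )
        data = ComplexMatrix(["G1", "G2"], times, vals)
        model = CVODEModel(
            1, [CVODETerm(0.5 + 0j, Var(2), 1), CVODETerm(0.25 + 0j, Var(1), -1)]
        )
        traj = integrate_decoupled(model, data)
        assert np.max(np.abs(traj.imag)) < 1e-12

    def test_divergent_model_raises(self):
        data = ComplexMatrix(["G1"], np.arange(10.0), np.full((1, 10), 5 + 0j))
        blowup = CVODEModel(1, [CVODETerm(50 + 0j, Binary("*", Var(1), Var(1)), 1)])
        with pytest.raises(DivergenceError):
            integrate_decoupled(blowup, data)

    def test_system_slot_mismatch_rejected(self):
        m1 = CVODEModel(1, [CVODETerm(1 + 0j, Var(1), 1)])
        with pytest.raises(ModelError):
            CVODESystem([m1, m1])


class TestSerialization:
    def test_model_dict_round_trip(self):
        model = sos_polB_model()
        again = CVODEModel.from_dict(model.to_dict())
        assert again.target == model.target
        assert np.allclose(again.coefficients, model.coefficients)
        assert [t.sign for t in again.terms] == [t.sign for t in model.terms]
        assert again.regulators() == model.regulators()
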