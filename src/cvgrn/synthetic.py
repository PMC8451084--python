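"""Ground-truth network + time-series generator for offline validation.

Builds random complex-valued ODE systems with known regulator sets, then
integrates them as a coupled system (all genes simultaneously — unlike
fitting, which is decoupled) and converts the complex trajectory to a real
expression matrix.  This deliberately mirrors how the inference method
meets real data: the generator and the fitter do not share an integration
scheme.

For recovery studies the generator supports real-valued coefficients with
the ``embed`` conversion mode.  In that configuration the simulated
trajectory stays real, the real projection is lossless, and "the true
model" is exactly a member of the search class on the observed data; with
complex coefficients every conversion mode's real projection discards
information, so exact recovery is only approximate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ExpressionMatrix, complex_to_real_values, normalize, real_to_complex_values
from .grammar import default_grammar, random_derivation
from .inference import GeneNetwork
from .model import (
    DIVERGENCE_BOUND,
    CompiledStructure,
    CVODEModel,
    CVODESystem,
    CVODETerm,
    terms_from_tree,
)

__all__ = ["SyntheticSpec", "SyntheticError", "random_system", "simulate", "generate_dataset"]

#: stability screen: reject systems whose trajectory magnitude exceeds this
STABILITY_BOUND = 1e3


class SyntheticError(RuntimeError):
    pass


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic data set.

    Defaults describe a small, noise-free benchmark: a handful of genes,
    sparse regulation, one or two additive terms per gene with unit-scale
    coefficients, and 40 samples at spacing 0.2 (matching the training
    window length used throughout the package).
    """

    m: int = 2
    edge_density: float = 0.3  # P(j regulates i) per ordered pair
    terms_range: tuple[int, int] = (1, 2)  # additive terms per gene
    coefficient_radius: float = 1.0  # uniform box half-width per re/im part
    real_coefficients: bool = False  # True -> imaginary parts are zero
    term_depth: int = 4  # depth budget per term subtree
    n_points: int = 40
    dt: float = 0.2
    noise_sd: float = 0.0
    mode: str = "embed"  # complex -> real conversion of the trajectory
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not (0 < self.edge_density <= 1):
            raise ValueError("edge_density must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.terms_range
        if not (1 <= lo <= hi):
            raise ValueError("terms_range must satisfy 1 <= lo <= hi")


def _random_model(
    spec: SyntheticSpec, target: int, rng: np.random.Generator
) -> CVODEModel:
    candidates = list(range(1, spec.m + 1))
    mask = rng.random(spec.m) < spec.edge_density
    regulators = [j for j, keep in zip(candidates, mask) if keep]
    if not regulators:
        regulators = [candidates[int(rng.integers(spec.m))]]
    grammar = default_grammar(
        len(regulators), var_names=[f"x_{j}" for j in regulators]
    )
    lo, hi = spec.terms_range
    k = int(rng.integers(lo, hi + 1))
    terms = []
    for _ in range(k):
        tree = random_derivation(grammar, spec.term_depth, rng, symbol="expr")
        (sign, expr), *rest = terms_from_tree(tree)
        # a term subtree may itself split into several signed terms; keep all
        for s, e in [(sign, expr)] + rest:
            re = spec.coefficient_radius * (2 * rng.random() - 1)
            im = 0.0 if spec.real_coefficients else spec.coefficient_radius * (
                2 * rng.random() - 1
            )
            terms.append(CVODETerm(complex(re, im), e, s))
    return CVODEModel(target, terms, n_genes=spec.m)


def _functionally_depends(model: CVODEModel, m: int, rng: np.random.Generator) -> bool:
    """True iff the RHS responds to every syntactic regulator.

    Random expression trees can yield terms such as x_j / x_j or x_j - x_j
    in which a variable appears but has no effect; with such a term the
    gold-standard edge would be unrecoverable from data by construction.
    Probes each regulator with finite differences at a few random states.
    """
    structure = CompiledStructure(model.terms)
    coeffs = model.coefficients
    states = 0.2 + 0.6 * rng.random((8, m)) + 0j
    for j in model.regulators():
        responds = False
        for z in states:
            base = structure.rhs_scalar(coeffs, z)
            bumped = z.copy()
            bumped[j - 1] += 0.1
            if abs(structure.rhs_scalar(coeffs, bumped) - base) > 1e-8:
                responds = True
                break
        if not responds:
            return False
    return True


def _default_initial_state(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Complex conversion of uniform values in [0.2, 0.8] (avoids the
    normalization boundaries)."""
    g0 = 0.2 + 0.6 * rng.random(spec.m)
    return np.asarray(real_to_complex_values(g0, spec.mode), dtype=complex)


def _integrate_coupled(
    system: CVODESystem,
    z0: np.ndarray,
    n_points: int,
    dt: float,
    substeps: int = 4,
    bound: float = DIVERGENCE_BOUND,
) -> np.ndarray:
    """Coupled RK4 of the full system; returns (m, n_points) complex."""
    structures = [CompiledStructure(mod.terms) for mod in system.models]
    coeffs = [mod.coefficients for mod in system.models]

    def rhs(z: np.ndarray) -> np.ndarray:
        return np.array(
            [s.rhs_scalar(c, z) for s, c in zip(structures, coeffs)], dtype=complex
        )

    h = dt / substeps
    z = np.asarray(z0, dtype=complex).copy()
    out = np.empty((len(system.models), n_points), dtype=complex)
    out[:, 0] = z
    for k in range(1, n_points):
        for _ in range(substeps):
            try:
                k1 = rhs(z)
                k2 = rhs(z + 0.5 * h * k1)
                k3 = rhs(z + 0.5 * h * k2)
                k4 = rhs(z + h * k3)
            except (OverflowError, ValueError) as err:
                raise SyntheticError("coupled simulation diverged") from err
            z = z + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            if not np.all(np.isfinite(z)) or np.max(np.abs(z)) > bound:
                raise SyntheticError("coupled simulation diverged")
        out[:, k] = z
    return out


def random_system(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[CVODESystem, GeneNetwork]:
    """Draw a random stable system and its gold-standard network.

    Regulator sets are drawn per ordered pair at ``edge_density`` (at least
    one per gene); term structures are shallow random derivation trees over
    those regulators.  The gold network is read off the generated models
    exactly as the inference stage does it, so the construction identity
    gold == extract_regulators holds by definition.  Systems are
    rejection-sampled (up to 100 draws) until the coupled trajectory stays
    within the stability screen.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    last_err: Exception | None = None

    def draw_model(target: int) -> CVODEModel:
        for _ in range(100):
            model = _random_model(spec, target, rng)
            if _functionally_depends(model, spec.m, rng):
                return model
        raise SyntheticError(
            f"no functionally non-degenerate model found for gene {target}"
        )

    for _ in range(100):
        system = CVODESystem([draw_model(i) for i in range(1, spec.m + 1)])
        z0 = _default_initial_state(spec, rng)
        try:
            traj = _integrate_coupled(
                system, z0, spec.n_points, spec.dt, bound=STABILITY_BOUND
            )
        except SyntheticError as err:
            last_err = err
            continue
        real = np.asarray(complex_to_real_values(traj, spec.mode), dtype=float)
        if np.min(np.ptp(real, axis=1)) < 0.05:
            # every gene must actually move, else its model is unidentifiable
            continue
        if np.max(np.abs(traj)) <= STABILITY_BOUND:
            edges = frozenset(
                (j, mod.target) for mod in system.models for j in mod.regulators()
            )
            network = GeneNetwork(
                tuple(f"G{i}" for i in range(1, spec.m + 1)), edges
            )
            system._z0 = z0  # cached draw so generate_dataset reuses it
            return system, network
    raise SyntheticError(
        "no stable system found in 100 draws; try a smaller coefficient_radius"
    ) from last_err


def simulate(
    system: CVODESystem,
    z0: np.ndarray,
    n_points: int,
    dt: float,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    mode: str = "embed",
    do_normalize: bool = True,
) -> ExpressionMatrix:
    """Coupled integration -> real conversion -> noise -> normalization.

    ``do_normalize=False`` keeps the raw converted scale, which preserves
    the generating system as the exact ground truth of the observed series
    (min-max rescaling would compose an affine map into the data that the
    generating coefficients know nothing about).
    """
    if rng is None:
        rng = np.random.default_rng()
    traj = _integrate_coupled(system, z0, n_points, dt)
    real = np.asarray(complex_to_real_values(traj, mode), dtype=float)
    if noise_sd > 0:
        real = real + rng.normal(0.0, noise_sd, size=real.shape)
    times = dt * np.arange(n_points)
    mat = ExpressionMatrix([f"G{i + 1}" for i in range(real.shape[0])], times, real)
    if do_normalize:
        mat = normalize(mat, scope="per-gene")
    return mat


def generate_dataset(
    spec: SyntheticSpec, rng: np.random.Generator | None = None, do_normalize: bool = True
) -> tuple[ExpressionMatrix, GeneNetwork, CVODESystem]:
    """Convenience wrapper: draw a system and simulate its expression matrix."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    system, network = random_system(spec, rng)
    data = simulate(
        system,
        system._z0,
        spec.n_points,
        spec.dt,
        spec.noise_sd,
        rng,
        mode=spec.mode,
        do_normalize=do_normalize,
    )
    return data, network, system
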