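"""Per-gene model search and network assembly.

Each gene's regulatory inputs are inferred independently: the expression
matrix is normalized, embedded in the complex plane, and a model for gene i
is evolved on the training window.  Gene j regulates gene i exactly when
x_j appears in gene i's optimal model — no coefficient-magnitude threshold
is applied.  The candidate edge space is all m^2 ordered pairs, self-loops
included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import (
    ComplexMatrix,
    ExpressionMatrix,
    complex_to_real_values,
    normalize,
    real_to_complex,
)
from .evaluation import rmse
from .gggp import GGGPParams, evolve
from .grammar import default_grammar
from .model import CVODEModel, CVODESystem, integrate_decoupled
from . import __version__ as _pkg_version

__all__ = [
    "GeneNetwork",
    "InferenceResult",
    "infer_network",
    "predict",
    "network_to_tsv",
    "network_from_tsv",
]


class InferenceError(ValueError):
    pass


@dataclass(frozen=True)
class GeneNetwork:
    """Directed regulator -> target edge set over 1-based gene indices."""

    gene_ids: tuple[str, ...]
    edges: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "edges", frozenset(self.edges))
        m = len(self.gene_ids)
        for r, t in self.edges:
            if not (1 <= r <= m and 1 <= t <= m):
                raise InferenceError(f"edge ({r}, {t}) outside 1..{m}")

    @property
    def m(self) -> int:
        return len(self.gene_ids)


@dataclass
class InferenceResult:
    network: GeneNetwork
    system: CVODESystem
    fitness: list[float]  # training RMSE per gene
    test_rmse: list[float]  # held-out RMSE per gene (empty if no test window)
    config: dict  # full parameter/seed/mode snapshot

    def __post_init__(self) -> None:
        expected = frozenset(
            (j, model.target)
            for model in self.system.models
            for j in model.regulators()
        )
        if expected != self.network.edges:
            raise InferenceError("network does not match the models' regulator sets")


def _config_snapshot(params: GGGPParams, seed: int, mode: str, scope: str, n_train: int) -> dict:
    cfa = params.cfa
    return {
        "package_version": _pkg_version,
        "seed": seed,
        "conversion_mode": mode,
        "normalization_scope": scope,
        "n_train": n_train,
        "gggp": {
            "population": params.population,
            "crossover_rate": params.crossover_rate,
            "mutation_rate": params.mutation_rate,
            "generations": params.generations,
            "tournament_size": params.tournament_size,
            "elitism": params.elitism,
            "cfa_every": params.cfa_every,
            "max_depth_init": params.max_depth_init,
            "max_depth": params.max_depth,
            "parsimony": params.parsimony,
            "substeps": params.substeps,
        },
        "cfa": {
            "population": cfa.population,
            "alpha": cfa.alpha,
            "beta0": cfa.beta0,
            "gamma": cfa.gamma,
            "iterations": cfa.iterations,
            "init_radius": cfa.init_radius,
        },
    }


def infer_network(
    data: ExpressionMatrix,
    n_train: int,
    params: GGGPParams | None = None,
    seed: int = 0,
    mode: str = "phase45",
    scope: str = "per-gene",
    do_normalize: bool = True,
    log: bool = False,
) -> InferenceResult:
    """Infer a directed gene network from a time-series expression matrix.

    The first ``n_train`` time points drive the model search; the remainder
    are a held-out window scored by prediction RMSE (integration restarts
    from the last training sample).  Per-gene searches are independent, with
    gene i's generator seeded as seed + i so results do not depend on
    execution order.
    """
    params = params or GGGPParams()
    if do_normalize:
        data = normalize(data, scope=scope)
    const = [g for g, row in zip(data.gene_ids, data.values) if np.ptp(row) == 0]
    if const:
        warnings.warn(f"constant genes processed as-is: {const}", stacklevel=2)
    if n_train >= data.n:
        raise InferenceError(f"n_train={n_train} needs held-out points (n={data.n})")

    z = real_to_complex(data, mode)
    train = ComplexMatrix(z.gene_ids, z.times[:n_train], z.values[:, :n_train])
    grammar = default_grammar(data.m)

    models: list[CVODEModel] = []
    fitness: list[float] = []
    test_rmse: list[float] = []
    for i in range(1, data.m + 1):
        rng = np.random.default_rng(seed + i)
        result = evolve(i, train, grammar, params, rng, mode=mode)
        model = result.best.structure().model(result.best.coefficients, i)
        models.append(model)
        fitness.append(result.best.fitness)
        traj = integrate_decoupled(model, z, n_train - 1, data.n - 1, params.substeps)
        pred = complex_to_real_values(traj[1:], mode)
        obs = complex_to_real_values(z.values[i - 1, n_train:], mode)
        test_rmse.append(rmse(pred, obs))
        if log:
            print(
                f"[gene {i}/{data.m}] fit={fitness[-1]:.6g} "
                f"test={test_rmse[-1]:.6g} model={model.to_infix(data.gene_ids)}"
            )

    edges = frozenset(
        (j, model.target) for model in models for j in model.regulators()
    )
    network = GeneNetwork(tuple(data.gene_ids), edges)
    return InferenceResult(
        network,
        CVODESystem(models),
        fitness,
        test_rmse,
        _config_snapshot(params, seed, mode, scope, n_train),
    )


def predict(
    result: InferenceResult,
    data: ExpressionMatrix,
    start: int = 0,
    stop: int | None = None,
    substeps: int = 4,
) -> ExpressionMatrix:
    """Per-gene decoupled integration over [start, stop], back-converted to
    the real scale.  ``data`` must already be on the fitted (normalized)
    scale."""
    mode = result.config.get("conversion_mode", "phase45")
    if stop is None:
        stop = data.n - 1
    if not (0 <= start < stop <= data.n - 1):
        raise InferenceError(f"invalid prediction range [{start}, {stop}]")
    z = real_to_complex(data, mode)
    rows = []
    for model in result.system.models:
        traj = integrate_decoupled(model, z, start, stop, substeps)
        rows.append(complex_to_real_values(traj, mode))
    return ExpressionMatrix(
        data.gene_ids, data.times[start : stop + 1], np.vstack(rows)
    )


# ---------------------------------------------------------------------------
# Plain-text serialization
# ---------------------------------------------------------------------------


def network_to_tsv(network: GeneNetwork, path: str | Path) -> None:
    """Two-column TSV edge list (regulator <TAB> target gene ids), with header."""
    lines = ["regulator\ttarget"]
    for r, t in sorted(network.edges):
        lines.append(f"{network.gene_ids[r - 1]}\t{network.gene_ids[t - 1]}")
    Path(path).write_text("\n".join(lines) + "\n")


def network_from_tsv(path: str | Path, gene_ids: Sequence[str]) -> GeneNetwork:
    gene_ids = list(gene_ids)
    index = {g: k + 1 for k, g in enumerate(gene_ids)}
    edges = set()
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines):
        if lineno == 0 and line.strip().lower().startswith("regulator"):
            continue
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise InferenceError(f"{path}: bad edge line {lineno + 1}: {line!r}")
        r, t = (p.strip() for p in parts)
        if r not in index or t not in index:
            raise InferenceError(f"{path}: unknown gene in edge {line!r}")
        edges.add((index[r], index[t]))
    return GeneNetwork(tuple(gene_ids), frozenset(edges))
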