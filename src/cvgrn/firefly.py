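"""Complex-valued firefly algorithm (CFA).

A swarm of K-dimensional complex positions (coefficient vectors) is scored
by a real objective; brightness is the negated objective, so dimmer
fireflies move toward brighter ones.  Real and imaginary parts are updated
in parallel: the canonical firefly rule

    p <- p + beta0 * exp(-gamma * r^2) * (q - p) + alpha * (u - 1/2)

is applied coordinate-wise on the 2K-dimensional real/imaginary unfolding,
with r the Euclidean distance between unfoldings and u ~ Uniform(0,1) drawn
per coordinate.  Within an iteration fireflies are ranked once by the
previous brightness (ties broken by index); for each firefly, from the
brightest down, every strictly dimmer firefly takes one step toward its
current position, the single brightest firefly takes a pure random step,
and all positions are re-scored together.  The best position ever visited
is retained, so the best-fitness trace is non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["CFAParams", "CFAResult", "CFAError", "firefly_move", "cfa_optimize"]


class CFAError(RuntimeError):
    """Objective failure inside the swarm loop."""


@dataclass
class CFAParams:
    """Swarm settings: population 100 and step size 0.02 follow the method's
    published operating point; the remaining knobs are standard firefly
    defaults.

    The absorption coefficient is scaled to the initialization box,
    gamma = 1/L^2 with L = 2*init_radius: with an unscaled gamma of order 1
    the attraction term exp(-gamma r^2) underflows for typical inter-firefly
    distances in more than one complex dimension and the swarm degenerates
    into a pure random walk.
    """

    population: int = 100
    alpha: float = 0.02  # random-step size
    beta0: float = 1.0  # attractiveness at distance zero
    gamma: float = 0.01  # light absorption, 1/(2*init_radius)^2
    iterations: int = 50
    init_radius: float = 5.0  # uniform init box half-width (per re/im part)
    alpha_decay: float = 1.0  # optional geometric decay per iteration
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if min(self.alpha, self.beta0, self.gamma) <= 0:
            raise ValueError("alpha, beta0 and gamma must be positive")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")


@dataclass
class CFAResult:
    position: np.ndarray  # best-ever complex coefficient vector (K,)
    fitness: float  # objective at that position
    trace: list[float]  # best-ever fitness per iteration (length iterations+1)


def _unfold(p: np.ndarray) -> np.ndarray:
    return np.concatenate([p.real, p.imag])


def _fold(x: np.ndarray) -> np.ndarray:
    k = x.shape[-1] // 2
    return x[..., :k] + 1j * x[..., k:]


def firefly_move(
    p: np.ndarray,
    q: np.ndarray,
    params: CFAParams,
    rng: np.random.Generator,
    alpha: float | None = None,
) -> np.ndarray:
    """One attraction step of firefly at ``p`` toward brighter ``q``."""
    p = np.asarray(p, dtype=complex)
    q = np.asarray(q, dtype=complex)
    x, y = _unfold(p), _unfold(q)
    r2 = float(np.sum((y - x) ** 2))
    a = params.alpha if alpha is None else alpha
    u = rng.random(x.shape[0])
    x_new = x + params.beta0 * np.exp(-params.gamma * r2) * (y - x) + a * (u - 0.5)
    return _fold(x_new)


def cfa_optimize(
    objective: Callable[[np.ndarray], float],
    k: int,
    params: CFAParams | None = None,
    rng: np.random.Generator | None = None,
    x0: Sequence[complex] | None = None,
    batch_objective: Callable[[np.ndarray], np.ndarray] | None = None,
) -> CFAResult:
    """Minimize a real objective over K complex coefficients.

    ``objective`` maps a (K,) complex vector to a finite float (or a large
    penalty).  ``batch_objective``, if given, maps a (K, B) array to (B,)
    fitness values and is used for whole-swarm scoring.  ``x0`` seeds
    firefly 0 with an incumbent solution, which makes refitting monotone
    (the result is never worse than the incumbent).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    params = params or CFAParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)

    P = params.population
    pos = params.init_radius * (2.0 * rng.random((P, 2 * k)) - 1.0)
    if x0 is not None:
        pos[0] = _unfold(np.asarray(x0, dtype=complex))

    def score_all(positions: np.ndarray, iteration: int) -> np.ndarray:
        folded = _fold(positions)  # (P, K)
        if batch_objective is not None:
            fit = np.asarray(batch_objective(folded.T), dtype=float)
        else:
            fit = np.empty(P)
            for idx in range(P):
                try:
                    fit[idx] = float(objective(folded[idx]))
                except Exception as exc:  # noqa: BLE001 - context per contract
                    raise CFAError(
                        f"objective failed for firefly {idx} at iteration {iteration}"
                    ) from exc
        if not np.all(np.isfinite(fit)):
            raise CFAError("objective returned a non-finite value")
        return fit

    fit = score_all(pos, 0)
    best_idx = int(np.argmin(fit))  # argmin is stable: ties -> lowest index
    best_fit = float(fit[best_idx])
    best_pos = pos[best_idx].copy()
    trace = [best_fit]

    alpha = params.alpha
    for it in range(1, params.iterations + 1):
        order = np.argsort(fit, kind="stable")
        for j in order:
            dimmer = fit > fit[j]
            dimmer[j] = False
            nd = int(dimmer.sum())
            if nd == 0:
                continue
            diff = pos[j][None, :] - pos[dimmer]
            r2 = np.sum(diff * diff, axis=1)
            u = rng.random((nd, 2 * k))
            pos[dimmer] += (
                params.beta0 * np.exp(-params.gamma * r2)[:, None] * diff
                + alpha * (u - 0.5)
            )
        # brightest firefly: pure random walk (prevents stagnation)
        pos[order[0]] += alpha * (rng.random(2 * k) - 0.5)
        fit = score_all(pos, it)
        it_best = int(np.argmin(fit))
        if fit[it_best] < best_fit:
            best_fit = float(fit[it_best])
            best_pos = pos[it_best].copy()
        trace.append(best_fit)
        alpha *= params.alpha_decay

    return CFAResult(_fold(best_pos), best_fit, trace)
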