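"""Canonical validation studies run by the test suite and acceptance script.

The edge-recovery study is a scaled-down stand-in for benchmark inference
on real expression datasets (which require external downloads and long
stochastic searches): small seeded synthetic systems with known regulator
sets, fitted by the full pipeline, scored by exact regulator-set recovery
and held-out prediction RMSE.

Study conditions (fixed, not tuning knobs): 2 genes, one generating term
per gene, real generating coefficients observed through the lossless
``embed`` projection, no noise, 46 samples at spacing 0.2 split 40/6 —
mirroring the benchmark protocol of searching on the first 40 time points
and testing on the rest.  GGGP runs population 50 for 30 generations with
the standard CFA settings (population 100, step size 0.02).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .firefly import CFAParams
from .gggp import GGGPParams
from .inference import infer_network
from .synthetic import SyntheticSpec, generate_dataset

__all__ = ["RecoveryRun", "RecoveryStudy", "edge_recovery_study", "study_params"]


@dataclass
class RecoveryRun:
    seed: int
    gold_edges: frozenset
    inferred_edges: frozenset
    exact: bool
    test_rmse: float


@dataclass
class RecoveryStudy:
    runs: list[RecoveryRun]
    rmse_threshold: float

    @property
    def n_success(self) -> int:
        return sum(r.exact and r.test_rmse < self.rmse_threshold for r in self.runs)

    @property
    def recovery_rate(self) -> float:
        return self.n_success / len(self.runs)

    @property
    def mean_test_rmse(self) -> float:
        return float(np.mean([r.test_rmse for r in self.runs]))


def study_params(generations: int = 30, population: int = 50) -> GGGPParams:
    return GGGPParams(
        population=population, generations=generations, cfa=CFAParams()
    )


def edge_recovery_study(
    n_seeds: int = 10,
    data_seed_base: int = 1000,
    infer_seed_base: int = 2000,
    noise_sd: float = 0.0,
    generations: int = 30,
    population: int = 50,
    rmse_threshold: float = 0.05,
) -> RecoveryStudy:
    """Run the recovery study over ``n_seeds`` independent systems.

    Each replicate draws its own 2-gene system (dataset seed
    ``data_seed_base + s``), fits the full pipeline (inference seed
    ``infer_seed_base + s``), and records whether the inferred regulator
    set equals the gold standard exactly plus the mean held-out RMSE.
    """
    runs: list[RecoveryRun] = []
    for s in range(n_seeds):
        spec = SyntheticSpec(
            m=2,
            terms_range=(1, 1),
            real_coefficients=True,
            mode="embed",
            n_points=46,
            dt=0.2,
            noise_sd=noise_sd,
            seed=int(data_seed_base + s),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            data, gold, _system = generate_dataset(spec, do_normalize=False)
            result = infer_network(
                data,
                40,
                study_params(generations, population),
                seed=int(infer_seed_base + s),
                mode="embed",
                do_normalize=False,
            )
        mean_rmse = float(np.mean(result.test_rmse))
        runs.append(
            RecoveryRun(
                seed=s,
                gold_edges=gold.edges,
                inferred_edges=result.network.edges,
                exact=result.network.edges == gold.edges,
                test_rmse=mean_rmse,
            )
        )
    return RecoveryStudy(runs, rmse_threshold)
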