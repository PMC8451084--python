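"""Prediction-error and network-accuracy metrics.

Network accuracy is scored over all m^2 ordered gene pairs (self-loops
included): an inferred edge present in the gold standard is a true
positive, and so on.  Sensitivity Sn = TP/(TP+FN) is the fraction of true
regulations recovered; specificity Sp = TN/(TN+FP) is the fraction of
non-regulations correctly absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "EvaluationError",
    "MetricUndefinedError",
    "ConfusionCounts",
    "rmse",
    "confusion",
    "sensitivity",
    "specificity",
    "percent_change",
    "mean_rmse",
]


class EvaluationError(ValueError):
    pass


class MetricUndefinedError(EvaluationError):
    """Zero denominator: the requested metric is undefined."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @classmethod
    def from_positive_counts(
        cls, tp: int, fp: int, n_genes: int, n_gold: int
    ) -> "ConfusionCounts":
        """Build full counts from reported TP/FP, the gene count and the
        gold-edge count, using TN = m^2 - TP - FP - FN."""
        fn = n_gold - tp
        tn = n_genes * n_genes - tp - fp - fn
        return cls(tp, fp, tn, fn)


def rmse(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Root-mean-square error between two equal-length real series."""
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape:
        raise EvaluationError(f"length mismatch: {p.shape} vs {o.shape}")
    if p.size == 0:
        raise EvaluationError("series must be non-empty")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def confusion(inferred, gold, m: int | None = None) -> ConfusionCounts:
    """Confusion counts of an inferred directed network against a gold one.

    ``inferred``/``gold`` are GeneNetwork objects or plain edge sets of
    (regulator, target) 1-based index pairs; counts run over all m^2
    ordered pairs including self-loops.
    """
    inf_edges = set(getattr(inferred, "edges", inferred))
    gold_edges = set(getattr(gold, "edges", gold))
    inf_ids = getattr(inferred, "gene_ids", None)
    gold_ids = getattr(gold, "gene_ids", None)
    if inf_ids is not None and gold_ids is not None and list(inf_ids) != list(gold_ids):
        raise EvaluationError("inferred and gold networks cover different gene sets")
    if m is None:
        if inf_ids is not None:
            m = len(inf_ids)
        else:
            raise EvaluationError("m (gene count) required for plain edge sets")
    universe = {(i, j) for i in range(1, m + 1) for j in range(1, m + 1)}
    if not inf_edges <= universe or not gold_edges <= universe:
        raise EvaluationError(f"edges outside the {m}x{m} index range")
    tp = len(inf_edges & gold_edges)
    fp = len(inf_edges - gold_edges)
    fn = len(gold_edges - inf_edges)
    tn = m * m - tp - fp - fn
    return ConfusionCounts(tp, fp, tn, fn)


def sensitivity(c: ConfusionCounts) -> float:
    """Sn = TP / (TP + FN)."""
    if c.tp + c.fn == 0:
        raise MetricUndefinedError("no positive samples: sensitivity undefined")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """Sp = TN / (TN + FP)."""
    if c.tn + c.fp == 0:
        raise MetricUndefinedError("no negative samples: specificity undefined")
    return c.tn / (c.tn + c.fp)


def percent_change(base: float, new: float) -> float:
    """Relative decrease from ``base`` to ``new``, in percent."""
    if base <= 0:
        raise EvaluationError("baseline must be positive")
    return 100.0 * (base - new) / base


def mean_rmse(values: Sequence[float]) -> float:
    """Arithmetic mean of per-gene RMSE values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise EvaluationError("empty RMSE list")
    return float(np.mean(v))
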