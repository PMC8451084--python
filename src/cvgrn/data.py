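"""Expression-matrix I/O, normalization and real <-> complex conversion.

Gene-expression time series arrive as an m x n real matrix (genes x time
points).  The pipeline min-max normalizes each series to [0, 1], embeds it
in the complex plane for model fitting, and maps complex model output back
to the real scale for comparison with observations.

Three invertible conversion modes are provided:

``embed``
    z = g + 0i; back-conversion takes the real part.
``phase45`` (pipeline default)
    z = g * e^{i pi/4} — equal real and imaginary loading; back-conversion
    is the modulus.  A purely real embedding would make the imaginary parts
    of coefficients nearly unobservable in a real-valued fitness, defeating
    the point of a complex-valued model class.
``unit_phase``
    z = e^{i pi g} on the unit circle; back-conversion is arccos(Re z)/pi
    with clamping against numeric drift.
"""

from __future__ import annotations

import cmath
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "ExpressionMatrix",
    "ComplexMatrix",
    "MODES",
    "normalize",
    "real_to_complex",
    "complex_to_real",
    "complex_to_real_values",
    "real_to_complex_values",
    "load_matrix",
    "save_matrix",
    "split_train_test",
]

MODES = ("embed", "phase45", "unit_phase")

_PHASE45 = cmath.exp(1j * cmath.pi / 4)


class DataError(ValueError):
    """Malformed expression data or conversion request."""


@dataclass
class ExpressionMatrix:
    """Real m x n expression matrix with gene ids and time stamps."""

    gene_ids: list[str]
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        _check_matrix(self)
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression values must be finite (no missing data)")

    @property
    def m(self) -> int:
        return len(self.gene_ids)

    @property
    def n(self) -> int:
        return self.times.shape[0]


@dataclass
class ComplexMatrix:
    """Complex m x n matrix sharing the shape of its source ExpressionMatrix."""

    gene_ids: list[str]
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        _check_matrix(self)
        if not np.all(np.isfinite(self.values.real) & np.isfinite(self.values.imag)):
            raise DataError("complex values must be finite")

    @property
    def m(self) -> int:
        return len(self.gene_ids)

    @property
    def n(self) -> int:
        return self.times.shape[0]


def _check_matrix(x) -> None:
    if len(set(x.gene_ids)) != len(x.gene_ids):
        dupes = sorted({g for g in x.gene_ids if x.gene_ids.count(g) > 1})
        raise DataError(f"duplicate gene ids: {dupes}")
    if x.values.ndim != 2:
        raise DataError("values must be a 2-D matrix")
    if x.values.shape != (len(x.gene_ids), x.times.shape[0]):
        raise DataError(
            f"shape mismatch: {x.values.shape} vs "
            f"({len(x.gene_ids)} genes, {x.times.shape[0]} times)"
        )
    if x.times.shape[0] >= 2 and np.any(np.diff(x.times) <= 0):
        raise DataError("time stamps must be strictly increasing")


def normalize(x: ExpressionMatrix, scope: str = "per-gene") -> ExpressionMatrix:
    """Min-max normalize to [0, 1]: g' = (g - g_min) / (g_max - g_min).

    ``scope`` picks the min/max window: each gene's own series
    (``per-gene``, default) or the whole matrix (``global``).  A constant
    series maps to all zeros with a warning.
    """
    v = x.values
    if scope == "per-gene":
        lo = v.min(axis=1, keepdims=True)
        hi = v.max(axis=1, keepdims=True)
    elif scope == "global":
        lo = np.full((x.m, 1), v.min())
        hi = np.full((x.m, 1), v.max())
    else:
        raise DataError(f"unknown normalization scope {scope!r}")
    span = hi - lo
    flat = span[:, 0] == 0
    if flat.any():
        names = [x.gene_ids[i] for i in np.nonzero(flat)[0]]
        warnings.warn(
            f"constant series set to 0 during normalization: {names}", stacklevel=2
        )
    safe = np.where(span == 0, 1.0, span)
    out = np.where(span == 0, 0.0, (v - lo) / safe)
    return ExpressionMatrix(x.gene_ids, x.times, out)


def real_to_complex_values(g: np.ndarray | float, mode: str = "phase45"):
    """Elementwise real -> complex embedding (values expected in [0, 1])."""
    g = np.asarray(g, dtype=float)
    if mode == "embed":
        out = g.astype(complex)
    elif mode == "phase45":
        out = g * _PHASE45
    elif mode == "unit_phase":
        out = np.cos(np.pi * g) + 1j * np.sin(np.pi * g)
    else:
        raise DataError(f"unknown conversion mode {mode!r}")
    return out if out.ndim else complex(out)


def complex_to_real_values(z: np.ndarray | complex, mode: str = "phase45"):
    """Elementwise complex -> real, inverse of ``real_to_complex_values``."""
    z = np.asarray(z, dtype=complex)
    if mode == "embed":
        out = z.real
    elif mode == "phase45":
        out = np.abs(z)
    elif mode == "unit_phase":
        out = np.arccos(np.clip(z.real, -1.0, 1.0)) / np.pi
    else:
        raise DataError(f"unknown conversion mode {mode!r}")
    return out if out.ndim else float(out)


def real_to_complex(x: ExpressionMatrix, mode: str = "phase45") -> ComplexMatrix:
    return ComplexMatrix(x.gene_ids, x.times, real_to_complex_values(x.values, mode))


def complex_to_real(z: ComplexMatrix, mode: str = "phase45") -> ExpressionMatrix:
    return ExpressionMatrix(z.gene_ids, z.times, complex_to_real_values(z.values, mode))


def load_matrix(path: str | Path, dialect: str | None = None) -> ExpressionMatrix:
    """Read a TSV/CSV matrix: first column gene ids, header row time stamps.

    ``dialect`` forces the separator ("tsv"/"csv"); otherwise it is picked
    from the file extension.  A non-numeric header means time stamps are
    absent and indices 0 … n-1 are assumed.
    """
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else "csv"
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise DataError(f"{path.name}: duplicate gene ids {dupes}")
    try:
        times = np.array([float(c) for c in df.columns])
    except ValueError:
        times = np.arange(df.shape[1], dtype=float)
    values = np.empty(df.shape, dtype=float)
    for i, gene in enumerate(gene_ids):
        for j, col in enumerate(df.columns):
            cell = df.iat[i, j]
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise DataError(
                    f"{path.name}: non-numeric cell {cell!r} at gene {gene!r}, "
                    f"column {col!r}"
                ) from None
    if np.any(np.isnan(values)):
        i, j = map(int, np.argwhere(np.isnan(values))[0])
        raise DataError(
            f"{path.name}: missing value at gene {gene_ids[i]!r}, column {j}"
        )
    return ExpressionMatrix(gene_ids, times, values)


def save_matrix(x: ExpressionMatrix, path: str | Path, dialect: str | None = None) -> None:
    """Write a matrix in the load_matrix layout (>= 6 significant digits)."""
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else "csv"
    sep = "\t" if dialect == "tsv" else ","
    df = pd.DataFrame(
        x.values, index=x.gene_ids, columns=[f"{t:.10g}" for t in x.times]
    )
    df.index.name = "gene"
    df.to_csv(path, sep=sep, float_format="%.10g")


def split_train_test(
    x: ExpressionMatrix, n_train: int
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Prefix/suffix split by time index (no shuffling — this is a time series)."""
    if not (1 < n_train < x.n):
        raise DataError(f"n_train must satisfy 1 < n_train < {x.n}, got {n_train}")
    train = ExpressionMatrix(x.gene_ids, x.times[:n_train], x.values[:, :n_train])
    test = ExpressionMatrix(x.gene_ids, x.times[n_train:], x.values[:, n_train:])
    return train, test
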