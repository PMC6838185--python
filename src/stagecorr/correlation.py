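"""Interspecies stage-by-stage Pearson correlation matrices.

The central object is the matrix C whose entry ``C[i, j]`` is the Pearson
correlation, computed across a set of homologous gene pairs, between the
expression of stage ``i`` in one species and stage ``j`` in the other.  When
the stages are aligned (morphologically equivalent stages share an index) the
diagonal of C measures conservation of expression at equivalent stages; its
mean is the average correlation AC, and the position of its maximum is the
candidate phylotypic stage of the hourglass model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats


class ZeroVarianceWarning(UserWarning):
    """A correlation input had zero variance; r is reported as 0."""


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length vectors.

    A zero-variance input carries no stage-discriminating signal, so instead
    of failing the correlation is defined as 0 and a :class:`ZeroVarianceWarning`
    is emitted.  Raises ``ValueError`` on length mismatch or fewer than two
    observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.ndim != 1 or x.shape[0] < 2:
        raise ValueError("pearson requires 1-d vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(
            "zero-variance input to pearson; returning r = 0", ZeroVarianceWarning
        )
        return 0.0
    return float(stats.pearsonr(x, y).statistic)


def _standardize_columns(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each column (population sd); zero-variance columns become 0."""
    mu = m.mean(axis=0)
    sd = m.std(axis=0)
    degenerate = sd == 0
    z = m - mu
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(degenerate, 0.0, z / np.where(degenerate, 1.0, sd))
    return z, degenerate


def cross_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between every column of ``a`` and every column of ``b``.

    ``a`` and ``b`` are gene x stage matrices with identical, homolog-paired
    row order; genes are the observations.  Columns with zero variance yield
    r = 0 (with a warning), mirroring :func:`pearson`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("matrices must be row-paired (same gene count)")
    if a.shape[0] < 2:
        raise ValueError("at least 2 genes required")
    za, dega = _standardize_columns(a)
    zb, degb = _standardize_columns(b)
    if dega.any() or degb.any():
        warnings.warn(
            "zero-variance stage column(s); affected correlations set to 0",
            ZeroVarianceWarning,
        )
    c = za.T @ zb / a.shape[0]
    # guard against fp overshoot just past +/-1
    return np.clip(c, -1.0, 1.0)


@dataclass
class CorrelationMatrix:
    """Interspecies stage correlation matrix with its provenance."""

    values: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    species_a: str = "S1"
    species_b: str = "S2"
    n_genes: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_labels = tuple(str(l) for l in self.row_labels)
        self.col_labels = tuple(str(l) for l in self.col_labels)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("matrix shape does not match stage labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("correlation matrix contains non-finite entries")
        if np.any(np.abs(self.values) > 1 + 1e-9):
            raise ValueError("correlation entries must lie in [-1, 1]")

    @property
    def is_square(self) -> bool:
        return self.values.shape[0] == self.values.shape[1]

    def transpose(self) -> "CorrelationMatrix":
        return CorrelationMatrix(
            self.values.T,
            self.col_labels,
            self.row_labels,
            species_a=self.species_b,
            species_b=self.species_a,
            n_genes=self.n_genes,
        )


def stage_correlation_matrix(
    a: np.ndarray,
    b: np.ndarray,
    *,
    row_labels: Sequence[str] | None = None,
    col_labels: Sequence[str] | None = None,
    species: tuple[str, str] = ("S1", "S2"),
) -> CorrelationMatrix:
    """Build the full stage x stage correlation matrix C for a gene set.

    ``a`` and ``b`` are homolog-paired gene x stage matrices (rows in the same
    homolog order).  Stage counts may differ; the result is
    ``a.shape[1] x b.shape[1]``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = cross_correlation(a, b)
    if row_labels is None:
        row_labels = [f"stage{i + 1}" for i in range(a.shape[1])]
    if col_labels is None:
        col_labels = [f"stage{j + 1}" for j in range(b.shape[1])]
    return CorrelationMatrix(
        c,
        tuple(row_labels),
        tuple(col_labels),
        species_a=species[0],
        species_b=species[1],
        n_genes=a.shape[0],
    )


@dataclass
class CorrelationSummary:
    """AC and the diagonal ("hourglass") profile of a square correlation matrix."""

    ac: float
    ac_sd: float
    diagonal_profile: np.ndarray
    stage_labels: tuple[str, ...]
    peak_stage: str

    def __post_init__(self) -> None:
        self.diagonal_profile = np.asarray(self.diagonal_profile, dtype=float)


def summarize(matrix: CorrelationMatrix) -> CorrelationSummary:
    """AC (mean of the diagonal), its sd, and the diagonal conservation profile.

    AC = 1 means perfect correlation at every pair of equivalent stages, AC = 0
    no correlation.  Requires a square matrix built on an equal-length stage
    alignment; ``peak_stage`` is the stage label of the profile maximum, with
    ties broken toward the earliest stage.
    """
    if not matrix.is_square:
        raise ValueError("AC requires aligned equivalent stages (square matrix)")
    diag = np.diagonal(matrix.values).copy()
    ac = float(diag.mean())
    ac_sd = float(diag.std(ddof=1)) if diag.size > 1 else float("nan")
    peak = int(np.argmax(diag))  # argmax returns the first (earliest) maximum
    return CorrelationSummary(
        ac=ac,
        ac_sd=ac_sd,
        diagonal_profile=diag,
        stage_labels=matrix.row_labels,
        peak_stage=matrix.row_labels[peak],
    )
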