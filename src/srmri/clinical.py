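"""Contingency-table statistics for the clinical evaluation.

Two small computations accompany the imaging work: a Pearson chi-square
test of homogeneity comparing the distribution of meniscus-injury grades
(I-III) between arthroscopy — the diagnostic gold standard — and MRI
reading, and percentage summaries of treatment-method counts. Both
operate on small integer count tables; the study's printed tables ship
as packaged CSV fixtures.

The chi-square statistic is the classic ``sum (O - E)^2 / E`` with
expected counts from the row/column marginals, ``df = (r-1)(c-1)``, no
continuity correction, and the p-value from the chi-square upper tail.
Percentages are rounded half-up to two decimals, the convention used in
clinical reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .exceptions import DegenerateInputError, ShapeError

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "ProportionReport",
    "chi_square_homogeneity",
    "proportions",
    "load_grading_table",
    "load_treatment_counts",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Non-negative integer counts with row and column labels
    (e.g. rows = {arthroscopy, MRI}, columns = grades I-III)."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ShapeError("contingency table must be at least 2x2")
        if np.any(counts < 0):
            raise DegenerateInputError("counts must be non-negative")
        if len(self.row_labels) != counts.shape[0] or len(self.col_labels) != counts.shape[1]:
            raise ShapeError("label lengths must match the count matrix")


class ChiSquareResult(NamedTuple):
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class ProportionReport:
    """Counts with percentages (half-up, 2 decimals) of a category total."""

    labels: tuple[str, ...]
    counts: tuple[int, ...]
    percentages: tuple[float, ...]
    total: int

    def __str__(self) -> str:
        lines = [f"{lab}: {c} cases ({p:.2f}%)" for lab, c, p in
                 zip(self.labels, self.counts, self.percentages)]
        lines.append(f"total: {self.total}")
        return "\n".join(lines)


def chi_square_homogeneity(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square test of homogeneity across the table rows.

    Expected counts are ``row_total * col_total / grand_total``; a zero
    marginal makes them undefined and raises
    :class:`~srmri.exceptions.DegenerateInputError`.
    """
    obs = table.counts.astype(np.float64)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise DegenerateInputError("zero row or column marginal; expected counts undefined")
    expected = np.outer(row, col) / obs.sum()
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return ChiSquareResult(statistic, df, p)


def _round_half_up(x: Decimal) -> float:
    return float(x.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def proportions(counts: Sequence[int], labels: Sequence[str] | None = None) -> ProportionReport:
    """Per-category percentage of the total, rounded half-up to 2 decimals."""
    counts = [int(c) for c in counts]
    if any(c < 0 for c in counts):
        raise DegenerateInputError("counts must be non-negative")
    total = sum(counts)
    if total <= 0:
        raise DegenerateInputError("total count must be > 0")
    if labels is None:
        labels = tuple(f"category_{i+1}" for i in range(len(counts)))
    if len(labels) != len(counts):
        raise ShapeError("labels and counts must have equal length")
    pct = tuple(_round_half_up(Decimal(100 * c) / Decimal(total)) for c in counts)
    return ProportionReport(tuple(labels), tuple(counts), pct, total)


def _read_fixture(name: str) -> list[list[str]]:
    text = resources.files("srmri.data").joinpath(name).read_text()
    return [line.split(",") for line in text.strip().splitlines()]


def load_grading_table() -> ContingencyTable:
    """The study's grade I-III counts by method (arthroscopy vs MRI, n=60)."""
    rows = _read_fixture("meniscus_grading.csv")
    header = rows[0][1:]
    labels = tuple(r[0] for r in rows[1:])
    counts = np.array([[int(v) for v in r[1:]] for r in rows[1:]])
    return ContingencyTable(counts, labels, tuple(header))


def load_treatment_counts() -> tuple[tuple[str, ...], tuple[int, ...]]:
    """The study's treatment-method counts (n=60): suture, secondary
    resection, partial resection, total resection."""
    rows = _read_fixture("treatment_methods.csv")
    labels = tuple(r[0] for r in rows[1:])
    counts = tuple(int(r[1]) for r in rows[1:])
    return labels, counts
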