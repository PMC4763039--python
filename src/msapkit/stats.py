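"""Pearson chi-square tests of independence for count tables.

The analytic test uses the uncorrected Pearson statistic
``sum((O - E)^2 / E)`` with ``E = row_total * col_total / grand_total`` —
no Yates continuity correction, including for 2x2 tables.  A
margin-preserving permutation test (Patefield sampling of random tables
with the observed margins) is provided as a Monte-Carlo oracle for the
analytic p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "ContingencyResult",
    "DegenerateTableError",
    "pearson_chi_square",
    "chi_square_p_value",
    "permutation_chi_square",
]


class DegenerateTableError(ValueError):
    """Raised when a table has fewer than two informative rows or columns."""


@dataclass
class ContingencyTable:
    """A labelled r x c table of non-negative integer counts."""

    row_labels: List[str]
    col_labels: List[str]
    cells: Sequence[Sequence[int]]

    def __post_init__(self) -> None:
        arr = np.asarray(self.cells)
        if arr.ndim != 2:
            raise ValueError("cells must be a 2-D array of counts")
        if arr.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError(
                f"cell shape {arr.shape} does not match labels "
                f"({len(self.row_labels)} rows, {len(self.col_labels)} cols)"
            )
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            arr = arr.astype(np.int64)
        self.cells = arr

    def drop_zero_margins(self):
        """Return (reduced table, dropped-label list) after removing
        all-zero rows and columns."""
        arr = np.asarray(self.cells)
        keep_rows = arr.sum(axis=1) > 0
        keep_cols = arr.sum(axis=0) > 0
        dropped = [
            f"row:{lbl}" for lbl, k in zip(self.row_labels, keep_rows) if not k
        ] + [f"col:{lbl}" for lbl, k in zip(self.col_labels, keep_cols) if not k]
        reduced = ContingencyTable(
            [l for l, k in zip(self.row_labels, keep_rows) if k],
            [l for l, k in zip(self.col_labels, keep_cols) if k],
            arr[np.ix_(keep_rows, keep_cols)],
        )
        return reduced, dropped


@dataclass(frozen=True)
class ContingencyResult:
    statistic: float
    df: int
    p_value: float
    dropped: List[str] = field(default_factory=list)


def _informative(table: ContingencyTable) -> ContingencyTable:
    reduced, dropped = table.drop_zero_margins()
    r, c = np.asarray(reduced.cells).shape
    if r < 2:
        raise DegenerateTableError(
            f"fewer than two informative rows after dropping {dropped or 'nothing'}"
        )
    if c < 2:
        raise DegenerateTableError(
            f"fewer than two informative columns after dropping {dropped or 'nothing'}"
        )
    return reduced


def _pearson_statistic(observed: np.ndarray) -> float:
    observed = observed.astype(float)
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    expected = row @ col / observed.sum()
    return float(((observed - expected) ** 2 / expected).sum())


def pearson_chi_square(table: ContingencyTable) -> ContingencyResult:
    """Uncorrected Pearson chi-square test of independence.

    All-zero rows/columns are dropped (and reported in ``dropped``) with
    the degrees of freedom adjusted accordingly; a table left with fewer
    than two rows or columns raises :class:`DegenerateTableError`.
    """
    _, dropped = table.drop_zero_margins()
    reduced = _informative(table)
    observed = np.asarray(reduced.cells)
    statistic = _pearson_statistic(observed)
    df = (observed.shape[0] - 1) * (observed.shape[1] - 1)
    return ContingencyResult(statistic, df, chi_square_p_value(statistic, df), dropped)


def chi_square_p_value(statistic: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if statistic < 0:
        raise ValueError(f"statistic must be >= 0, got {statistic}")
    return float(sps.chi2.sf(statistic, df))


def permutation_chi_square(
    table: ContingencyTable, n_perm: int, seed: int
) -> float:
    """Monte-Carlo p-value from random tables with the observed margins.

    Tables are sampled under the null of independence conditional on both
    margins (Patefield's algorithm); the p-value uses the add-one
    convention ``(1 + #{stat* >= stat}) / (1 + n_perm)`` so it is never
    exactly zero.  Reproducible for a given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    reduced = _informative(table)
    observed = np.asarray(reduced.cells)
    stat = _pearson_statistic(observed)
    rng = np.random.default_rng(seed)
    row, col = observed.sum(axis=1), observed.sum(axis=0)
    sampler = sps.random_table(row, col)
    draws = np.asarray(sampler.rvs(n_perm, random_state=rng), dtype=float)
    draws = draws.reshape(n_perm, *observed.shape)
    # margins are fixed, so the expected table is the same for every draw
    expected = np.outer(row, col) / observed.sum()
    stats = ((draws - expected) ** 2 / expected).sum(axis=(1, 2))
    exceed = int(np.count_nonzero(stats >= stat - 1e-12))
    return (1 + exceed) / (1 + n_perm)
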