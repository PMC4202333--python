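"""Exact inference on 2xK contingency tables with fixed margins.

The test implemented here is the Freeman–Halton extension of Fisher's exact
test: conditioning on all margins, the cell configuration of a 2xK table
follows a multivariate hypergeometric law,

    P(table) = (prod_i r_i!) (prod_j c_j!) / (N! prod_ij n_ij!),

and the two-sided p-value sums P over every margin-consistent table whose
probability does not exceed the observed table's (probability ordering).
For two rows the support is indexed by the first row alone, so enumeration
walks the K-1 free cells of row 1 with feasibility bounds; at the sample
sizes of a transcriptome gene-set comparison (grand totals in the low
thousands, K = 3) that is a few tens of thousands of tables.

Log-probabilities use the log-gamma function so nothing overflows, and ties
between the observed probability and a candidate table's are resolved with
a small relative tolerance (default 1e-7), the common convention for exact
tests computed in floating point.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterator, Sequence
from typing import TYPE_CHECKING

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2, multivariate_hypergeom

from .errors import EnumerationLimitError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .annotation import CountSummary

__all__ = [
    "ContingencyTable2xK",
    "ExactTestResult",
    "log_table_probability",
    "enumerate_tables",
    "fisher_exact_2xk",
    "chisq_pvalue",
    "sample_null_tables",
]

#: Relative tolerance for probability ties in the two-sided sum.
DEFAULT_TIE_TOLERANCE = 1e-7

#: Default cap on the number of tables an exact test may enumerate.
DEFAULT_MAX_TABLES = 10_000_000


@dataclasses.dataclass(frozen=True)
class ContingencyTable2xK:
    """A 2-row contingency table of non-negative counts.

    Row 0 holds in-category counts, row 1 the complement; columns are the
    gene sets (or any K >= 2 groups).
    """

    cells: tuple[tuple[int, ...], tuple[int, ...]]

    def __post_init__(self) -> None:
        arr = np.asarray(self.cells)
        if arr.ndim != 2 or arr.shape[0] != 2 or arr.shape[1] < 2:
            raise ValidationError(
                f"expected a 2xK table with K >= 2, got shape {arr.shape}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise ValidationError("table cells must be integers")
            arr = arr.astype(np.int64)
        if np.any(arr < 0):
            raise ValidationError("table cells must be non-negative")
        object.__setattr__(
            self, "cells", tuple(tuple(int(x) for x in row) for row in arr)
        )

    @classmethod
    def from_rows(
        cls, in_category: Sequence[int], not_in_category: Sequence[int]
    ) -> "ContingencyTable2xK":
        return cls(cells=(tuple(in_category), tuple(not_in_category)))

    @classmethod
    def from_summary(
        cls, summary: "CountSummary", category: str
    ) -> "ContingencyTable2xK":
        """In-category vs. other *annotated* genes, one column per gene set.

        Unannotated genes are excluded: a gene without annotation carries no
        evidence about category membership, so denominators are annotated
        counts throughout the analysis.
        """
        if category not in summary.categories:
            raise ValidationError(
                f"unknown category {category!r}; have {summary.categories}"
            )
        observed = [summary.category_counts[category][s] for s in summary.sets]
        annotated = [summary.n_annotated[s] for s in summary.sets]
        return cls.from_rows(
            observed, [a - o for a, o in zip(annotated, observed)]
        )

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.cells, dtype=np.int64)

    @property
    def k(self) -> int:
        return len(self.cells[0])

    @property
    def row_totals(self) -> tuple[int, ...]:
        return tuple(int(x) for x in self.array.sum(axis=1))

    @property
    def col_totals(self) -> tuple[int, ...]:
        return tuple(int(x) for x in self.array.sum(axis=0))

    @property
    def grand_total(self) -> int:
        return int(self.array.sum())


@dataclasses.dataclass(frozen=True)
class ExactTestResult:
    """Outcome of a Freeman–Halton exact test."""

    p_value: float
    n_tables_enumerated: int
    observed_log_prob: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValidationError(f"p-value {self.p_value} outside (0, 1]")


def _log_prob_constant(row_totals: np.ndarray, col_totals: np.ndarray) -> float:
    total = row_totals.sum()
    return float(
        gammaln(row_totals + 1).sum()
        + gammaln(col_totals + 1).sum()
        - gammaln(total + 1)
    )


def log_table_probability(table: ContingencyTable2xK) -> float:
    """Log conditional probability of the table given all of its margins."""
    arr = table.array
    const = _log_prob_constant(arr.sum(axis=1), arr.sum(axis=0))
    return const - float(gammaln(arr + 1).sum())


def _row1_configurations(r1: int, col_totals: np.ndarray) -> np.ndarray:
    """All feasible first rows (n_tables, K) for row total *r1*.

    Column j of row 1 is bounded below by what the remaining columns cannot
    absorb and above by min(col_total_j, remaining row total); the last
    column is forced. Grown column-by-column as a vectorized frontier.
    """
    k = len(col_totals)
    tail = np.concatenate([np.cumsum(col_totals[::-1])[::-1][1:], [0]])
    prefix = np.zeros((1, 0), dtype=np.int64)
    remaining = np.array([r1], dtype=np.int64)
    for j in range(k - 1):
        lo = np.maximum(0, remaining - tail[j])
        hi = np.minimum(col_totals[j], remaining)
        counts = hi - lo + 1
        if np.any(counts <= 0):
            keep = counts > 0
            prefix, remaining, lo, counts = (
                prefix[keep],
                remaining[keep],
                lo[keep],
                counts[keep],
            )
        reps = np.repeat(np.arange(len(prefix)), counts)
        offsets = np.concatenate([np.arange(c) for c in counts])
        values = lo[reps] + offsets
        prefix = np.column_stack([prefix[reps], values])
        remaining = remaining[reps] - values
    # last column forced by the row total; feasibility guaranteed by bounds
    return np.column_stack([prefix, remaining])


def enumerate_tables(
    row_totals: Sequence[int], col_totals: Sequence[int]
) -> Iterator[ContingencyTable2xK]:
    """Yield every 2xK non-negative integer table with the given margins.

    Each table appears exactly once. Margins must be consistent
    (equal sums, non-negative, two row totals, K >= 2 column totals).
    """
    rows = np.asarray(row_totals, dtype=np.int64)
    cols = np.asarray(col_totals, dtype=np.int64)
    if rows.shape != (2,):
        raise ValidationError("expected exactly two row totals")
    if cols.ndim != 1 or len(cols) < 2:
        raise ValidationError("expected at least two column totals")
    if np.any(rows < 0) or np.any(cols < 0):
        raise ValidationError("margins must be non-negative")
    if rows.sum() != cols.sum():
        raise ValidationError(
            f"inconsistent margins: row sum {rows.sum()} != col sum {cols.sum()}"
        )
    for row1 in _row1_configurations(int(rows[0]), cols):
        yield ContingencyTable2xK.from_rows(row1, cols - row1)


def _enumeration_bound(r1: int, col_totals: np.ndarray) -> int:
    bound = 1
    for c in col_totals[:-1]:
        bound *= min(int(c), r1) + 1
        if bound > 10 * DEFAULT_MAX_TABLES:
            break
    return bound


def fisher_exact_2xk(
    table: ContingencyTable2xK,
    *,
    tie_rel_tol: float = DEFAULT_TIE_TOLERANCE,
    max_tables: int = DEFAULT_MAX_TABLES,
) -> ExactTestResult:
    """Two-sided Freeman–Halton exact test on a 2xK table.

    The p-value sums the conditional probabilities of all margin-consistent
    tables whose probability is <= the observed table's probability, with a
    relative tie tolerance of *tie_rel_tol*. On 2x2 tables this reduces to
    the classic two-sided Fisher exact test.

    Raises
    ------
    EnumerationLimitError
        If the enumeration would exceed *max_tables* tables; use
        :func:`chisq_pvalue` for such tables.
    """
    arr = table.array
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    r1 = int(rows[0])
    if _enumeration_bound(r1, cols) > max_tables:
        raise EnumerationLimitError(
            f"enumeration bound exceeds max_tables={max_tables}; "
            "fall back to chisq_pvalue for a table this large"
        )
    const = _log_prob_constant(rows, cols)
    row1 = _row1_configurations(r1, cols)
    if len(row1) > max_tables:
        raise EnumerationLimitError(
            f"{len(row1)} tables exceed max_tables={max_tables}"
        )
    log_probs = (
        const
        - gammaln(row1 + 1).sum(axis=1)
        - gammaln(cols[np.newaxis, :] - row1 + 1).sum(axis=1)
    )
    observed_log_prob = const - float(gammaln(arr + 1).sum())
    threshold = observed_log_prob + math.log1p(tie_rel_tol)
    p_value = float(np.exp(log_probs[log_probs <= threshold]).sum())
    p_value = min(p_value, 1.0)
    p_value = max(p_value, float(np.exp(observed_log_prob)))
    return ExactTestResult(
        p_value=p_value,
        n_tables_enumerated=len(row1),
        observed_log_prob=observed_log_prob,
    )


def chisq_pvalue(table: ContingencyTable2xK) -> float:
    """Pearson chi-square upper-tail p-value with K-1 degrees of freedom.

    The asymptotic counterpart of :func:`fisher_exact_2xk`, valid when all
    expected cell counts are comfortably positive.
    """
    arr = table.array
    rows = arr.sum(axis=1, keepdims=True)
    cols = arr.sum(axis=0, keepdims=True)
    expected = rows * cols / arr.sum()
    if np.any(expected <= 0):
        raise ValidationError("chi-square undefined: zero expected cell count")
    statistic = float(((arr - expected) ** 2 / expected).sum())
    return float(chi2.sf(statistic, df=table.k - 1))


def sample_null_tables(
    row_totals: Sequence[int],
    col_totals: Sequence[int],
    n_tables: int,
    rng: np.random.Generator,
) -> list[ContingencyTable2xK]:
    """Draw tables from the fixed-margin null (multivariate hypergeometric).

    Row 1 is drawn as the category-member allocation of ``row_totals[0]``
    items across columns of sizes ``col_totals``; row 2 is the complement.
    Used to check the exact test's finite-sample size empirically.
    """
    cols = np.asarray(col_totals, dtype=np.int64)
    r1 = int(row_totals[0])
    if r1 + int(row_totals[1]) != int(cols.sum()):
        raise ValidationError("inconsistent margins")
    draws = multivariate_hypergeom.rvs(
        m=cols, n=r1, size=n_tables, random_state=rng
    ).reshape(n_tables, len(cols))
    return [
        ContingencyTable2xK.from_rows(row1, cols - row1) for row1 in draws
    ]
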