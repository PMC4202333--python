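"""Observed/expected enrichment ratios with percentile-bootstrap intervals.

Under the null hypothesis that category membership (N-mt or N-cp) is
distributed homogeneously across gene sets, the expected number of
in-category genes in a set is

    E_set = p_pooled * n_annotated(set),

where p_pooled is the category proportion among all annotated genes pooled
across sets. The enrichment statistic is the ratio O_set / E_set, equal to
one under the null, above one for overrepresentation.

Confidence intervals come from a nonparametric bootstrap: the annotated
genes of the focal set are resampled with replacement (same size), the
in-category count is recomputed per replicate, and percentile bounds of the
replicate ratios are reported. By default the denominator E is held fixed at
its full-data value, so the interval describes sampling variation of the
observed count — the quantity the study design treats as random; an option
recomputes the pooled proportion per replicate for sensitivity analysis.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np

from .annotation import (
    CountSummary,
    GeneRecord,
    GeneSet,
    assign_category_flags,
    summarize_counts,
)
from .errors import UndefinedStatisticError, ValidationError

__all__ = [
    "RatioEstimate",
    "pooled_proportion",
    "expected_count",
    "obs_exp_ratio",
    "bootstrap_ci",
]

#: Replicates are resampled in chunks to bound peak memory.
_BOOT_CHUNK = 2048


@dataclasses.dataclass(frozen=True)
class RatioEstimate:
    """Observed count, expected count, their ratio, and a bootstrap CI.

    ``ci_low``/``ci_high`` are ``None`` for point estimates that were not
    bootstrapped (``n_boot == 0``).
    """

    observed: int
    expected: float
    ratio: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.expected <= 0:
            raise UndefinedStatisticError(
                f"expected count must be positive, got {self.expected}"
            )
        if abs(self.ratio - self.observed / self.expected) > 1e-12 * max(
            1.0, self.ratio
        ):
            raise ValidationError("ratio must equal observed/expected")


def pooled_proportion(summary: CountSummary, category: str) -> float:
    """Category proportion among all annotated genes, pooled over gene sets."""
    if category not in summary.categories:
        raise ValidationError(
            f"unknown category {category!r}; have {summary.categories}"
        )
    denominator = summary.total_annotated
    if denominator == 0:
        raise UndefinedStatisticError(
            "pooled proportion undefined: no annotated genes"
        )
    return summary.category_total(category) / denominator


def expected_count(
    summary: CountSummary, gene_set: GeneSet, category: str
) -> float:
    """Expected in-category count: pooled proportion x annotated genes in set."""
    if gene_set not in summary.sets:
        raise ValidationError(
            f"unknown gene set {gene_set}; have {summary.sets}"
        )
    return pooled_proportion(summary, category) * summary.n_annotated[gene_set]


def obs_exp_ratio(
    summary: CountSummary, gene_set: GeneSet, category: str
) -> RatioEstimate:
    """Point estimate of the observed/expected enrichment ratio (no CI)."""
    expected = expected_count(summary, gene_set, category)
    if expected <= 0:
        raise UndefinedStatisticError(
            f"expected count for {gene_set.value}/{category} is zero"
        )
    observed = summary.category_counts[category][gene_set]
    return RatioEstimate(
        observed=observed, expected=expected, ratio=observed / expected
    )


def bootstrap_ci(
    records: Sequence[GeneRecord],
    gene_set: GeneSet,
    category: str,
    *,
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
    level: float = 0.95,
    target_terms: Mapping[str, str] | None = None,
    flags: Mapping[str, np.ndarray] | None = None,
    expected: float | None = None,
    refit_expected: bool = False,
) -> RatioEstimate:
    """Percentile-bootstrap confidence interval for an enrichment ratio.

    Resamples the annotated genes of *gene_set* with replacement (same
    size), recomputes the in-category count per replicate, divides by the
    expected count, and returns the (1-level)/2 and 1-(1-level)/2 sample
    quantiles of the replicate ratios.

    Parameters
    ----------
    expected
        Override for the denominator; by default the full-data expected
        count (pooled proportion x set annotated size). Supplying a known
        true expected count makes the interval a CI for a known-denominator
        ratio, which is how coverage is validated in simulation.
    refit_expected
        If true, every replicate also resamples the *other* gene sets and
        recomputes the pooled proportion, propagating denominator
        uncertainty into the interval (sensitivity analysis).
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    if not 0 < level < 1:
        raise ValidationError(f"confidence level {level} outside (0, 1)")
    if flags is None:
        flags = assign_category_flags(records, target_terms)
    summary = summarize_counts(records, flags, target_terms=target_terms)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    in_category = np.asarray(flags[category], dtype=bool)
    annotated = np.fromiter(
        (r.annotated for r in records), dtype=bool, count=len(records)
    )
    member = np.fromiter(
        (r.set_label == gene_set for r in records), dtype=bool, count=len(records)
    )
    focal_flags = in_category[annotated & member]
    m = len(focal_flags)
    if m == 0:
        raise ValidationError(
            f"gene set {gene_set.value} has no annotated genes to resample"
        )

    point = obs_exp_ratio(summary, gene_set, category)
    exp_fixed = float(expected) if expected is not None else point.expected
    if exp_fixed <= 0:
        raise UndefinedStatisticError("expected count must be positive")

    if refit_expected:
        other_flags = [
            in_category[annotated & np.fromiter(
                (r.set_label == s for r in records), dtype=bool, count=len(records)
            )]
            for s in summary.sets
            if s != gene_set
        ]
        total_annotated = summary.total_annotated
        n_set = summary.n_annotated[gene_set]

    ratios = np.empty(n_boot)
    for start in range(0, n_boot, _BOOT_CHUNK):
        stop = min(start + _BOOT_CHUNK, n_boot)
        idx = rng.integers(0, m, size=(stop - start, m))
        obs_rep = focal_flags[idx].sum(axis=1)
        if refit_expected:
            pooled_rep = obs_rep.astype(float)
            for other in other_flags:
                mo = len(other)
                if mo:
                    jdx = rng.integers(0, mo, size=(stop - start, mo))
                    pooled_rep += other[jdx].sum(axis=1)
            exp_rep = pooled_rep / total_annotated * n_set
            ratios[start:stop] = np.where(
                exp_rep > 0, obs_rep / np.maximum(exp_rep, 1e-300), np.inf
            )
        else:
            ratios[start:stop] = obs_rep / exp_fixed
    alpha = 1.0 - level
    ci_low, ci_high = np.quantile(ratios, [alpha / 2, 1 - alpha / 2])
    observed = point.observed
    return RatioEstimate(
        observed=observed,
        expected=exp_fixed,
        ratio=observed / exp_fixed,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
        level=level,
    )
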