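"""Synthetic annotation tables with known generating parameters.

The generator emulates the annotation-table level of a sex-linked vs.
autosomal transcriptome study: three gene sets of configurable sizes, a
per-set probability that functional annotation succeeds, and — among
annotated genes — independent Bernoulli membership in each target category
(N-mt, N-cp) at a baseline proportion optionally scaled by a per-set
multiplicative enrichment effect rho (rho = 1 everywhere is the null).
Flagged genes receive the corresponding GO identifier plus 0-3 decoy GO
terms; decoys are syntactically valid and deliberately include near-miss
identifiers one digit away from the targets, so exact-membership matching
is exercised against realistic confusers.

Defaults reproduce the study conditions: set sizes 1,167 / 624 / 107
(autosomal / X-linked / X-hemizygous), a 90% annotation rate, and baseline
category proportions 301/1735 (N-mt) and 346/1735 (N-cp) — the pooled
proportions implied by the published count table.

``generate_table1_fixture`` is the deterministic companion: a table whose
count summary reproduces the published Table-1-style counts cell for cell
(synthetic gene identifiers; category assignments chosen to match the
printed marginals).
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .annotation import (
    DEFAULT_SET_ORDER,
    DEFAULT_TARGET_TERMS,
    GeneRecord,
    GeneSet,
)
from .errors import ValidationError

__all__ = [
    "TABLE1_COUNTS",
    "TABLE1_SET_SIZES",
    "SyntheticConfig",
    "generate_annotation_table",
    "generate_table1_fixture",
]

#: Published per-set counts: (n_total, n_annotated, n_mt, n_cp).
TABLE1_COUNTS: Mapping[GeneSet, tuple[int, int, int, int]] = {
    GeneSet.AUTOSOMAL: (1167, 1073, 194, 222),
    GeneSet.X_LINKED: (624, 567, 94, 102),
    GeneSet.X_HEMIZYGOUS: (107, 95, 13, 22),
}

TABLE1_SET_SIZES: Mapping[GeneSet, int] = {
    s: counts[0] for s, counts in TABLE1_COUNTS.items()
}

_TABLE1_TOTAL_ANNOTATED = sum(c[1] for c in TABLE1_COUNTS.values())

#: Baseline category proportions among annotated genes (study pooled values).
DEFAULT_BASE_PROPS: Mapping[str, float] = {
    "N-mt": sum(c[2] for c in TABLE1_COUNTS.values()) / _TABLE1_TOTAL_ANNOTATED,
    "N-cp": sum(c[3] for c in TABLE1_COUNTS.values()) / _TABLE1_TOTAL_ANNOTATED,
}

# Syntactically valid GO identifiers that are never target terms; the first
# two are near-misses one digit away from the mitochondrion/chloroplast ids.
_DECOY_TERMS = (
    "GO:0005740",
    "GO:0009508",
    "GO:0008150",
    "GO:0003674",
    "GO:0005575",
    "GO:0005634",
    "GO:0016020",
    "GO:0005737",
)

_SET_PREFIX = {
    GeneSet.AUTOSOMAL: "AUT",
    GeneSet.X_LINKED: "XLK",
    GeneSet.X_HEMIZYGOUS: "XHZ",
}


def _as_per_set(value, sets, name: str) -> dict[GeneSet, float]:
    if isinstance(value, Mapping):
        missing = [s for s in sets if s not in value]
        if missing:
            raise ValidationError(f"{name} missing entries for {missing}")
        return {s: float(value[s]) for s in sets}
    return {s: float(value) for s in sets}


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Generating parameters for a synthetic annotation table.

    Parameters
    ----------
    set_sizes
        Genes per gene set; defaults to the study sizes 1,167/624/107.
    annotation_rate
        Probability a gene obtains functional annotation, scalar or per
        set; default 0.90 (the study's reported annotation success rate).
    base_props
        Baseline per-category membership proportions among annotated genes.
    effects
        Multiplicative per-(category, set) enrichment ratios rho applied to
        the baseline proportion; 1.0 everywhere is the null. Configurations
        pushing any effective probability outside [0, 1] are rejected, not
        clamped.
    category_correlation
        Gaussian-copula correlation between the two category memberships of
        one gene (requires exactly two categories when nonzero); default 0,
        i.e. independent memberships.
    seed
        Seed for the single random stream driving generation.
    """

    set_sizes: Mapping[GeneSet, int] = dataclasses.field(
        default_factory=lambda: dict(TABLE1_SET_SIZES)
    )
    annotation_rate: float | Mapping[GeneSet, float] = 0.90
    base_props: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_BASE_PROPS)
    )
    effects: Mapping[str, Mapping[GeneSet, float]] = dataclasses.field(
        default_factory=dict
    )
    category_correlation: float = 0.0
    target_terms: Mapping[str, str] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_TARGET_TERMS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        sets = tuple(self.set_sizes)
        for s, n in self.set_sizes.items():
            if n < 0:
                raise ValidationError(f"set size for {s.value} is negative")
        rates = _as_per_set(self.annotation_rate, sets, "annotation_rate")
        for s, rate in rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(
                    f"annotation rate {rate} for {s.value} outside [0, 1]"
                )
        for category in self.base_props:
            if category not in self.target_terms:
                raise ValidationError(
                    f"category {category!r} has no target GO term"
                )
            for s in sets:
                p = self.effective_proportion(category, s)
                if not 0.0 <= p <= 1.0:
                    raise ValidationError(
                        f"effective proportion {p:.4f} for "
                        f"{category}/{s.value} outside [0, 1]"
                    )
        if not -1.0 <= self.category_correlation <= 1.0:
            raise ValidationError("category_correlation outside [-1, 1]")
        if self.category_correlation != 0.0 and len(self.base_props) != 2:
            raise ValidationError(
                "category_correlation requires exactly two categories"
            )

    def effective_proportion(self, category: str, gene_set: GeneSet) -> float:
        rho = self.effects.get(category, {}).get(gene_set, 1.0)
        return float(rho) * float(self.base_props[category])

    def to_dict(self) -> dict:
        """JSON-serializable record of the true generating parameters."""
        sets = tuple(self.set_sizes)
        rates = _as_per_set(self.annotation_rate, sets, "annotation_rate")
        return {
            "set_sizes": {s.value: int(n) for s, n in self.set_sizes.items()},
            "annotation_rate": {s.value: rates[s] for s in sets},
            "base_props": dict(self.base_props),
            "effects": {
                c: {s.value: float(r) for s, r in per_set.items()}
                for c, per_set in self.effects.items()
            },
            "effective_proportions": {
                c: {s.value: self.effective_proportion(c, s) for s in sets}
                for c in self.base_props
            },
            "category_correlation": self.category_correlation,
            "target_terms": dict(self.target_terms),
            "seed": self.seed,
        }


def _correlated_bernoulli(
    rng: np.random.Generator, probs: tuple[float, float], corr: float, n: int
) -> np.ndarray:
    """(n, 2) Bernoulli draws with Gaussian-copula correlation *corr*."""
    cov = np.array([[1.0, corr], [corr, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    thresholds = norm.ppf(probs)
    return z < thresholds[np.newaxis, :]


def generate_annotation_table(config: SyntheticConfig) -> list[GeneRecord]:
    """Draw one synthetic annotation table under *config*; reproducible by seed."""
    rng = np.random.default_rng(config.seed)
    sets = tuple(config.set_sizes)
    rates = _as_per_set(config.annotation_rate, sets, "annotation_rate")
    categories = tuple(config.base_props)
    records: list[GeneRecord] = []
    for gene_set in sets:
        n = int(config.set_sizes[gene_set])
        if n == 0:
            continue
        prefix = _SET_PREFIX.get(gene_set, gene_set.value[:3].upper())
        annotated = rng.random(n) < rates[gene_set]
        probs = [config.effective_proportion(c, gene_set) for c in categories]
        if config.category_correlation != 0.0 and len(categories) == 2:
            membership = _correlated_bernoulli(
                rng, (probs[0], probs[1]), config.category_correlation, n
            )
        else:
            membership = rng.random((n, len(categories))) < np.asarray(probs)
        membership &= annotated[:, np.newaxis]
        n_decoys = rng.integers(0, 4, size=n)
        decoy_picks = rng.integers(0, len(_DECOY_TERMS), size=(n, 3))
        for i in range(n):
            terms: set[str] = set()
            if annotated[i]:
                terms.update(
                    _DECOY_TERMS[j] for j in decoy_picks[i, : n_decoys[i]]
                )
                for c_idx, category in enumerate(categories):
                    if membership[i, c_idx]:
                        terms.add(config.target_terms[category])
            records.append(
                GeneRecord(
                    gene_id=f"{prefix}{i:06d}",
                    set_label=gene_set,
                    annotated=bool(annotated[i]),
                    go_terms=frozenset(terms),
                )
            )
    return records


def generate_table1_fixture() -> list[GeneRecord]:
    """Deterministic table reproducing the published count table exactly.

    Within each gene set the first ``n_mt`` annotated genes carry the
    mitochondrion term, the next ``n_cp`` the chloroplast term (the printed
    marginals leave the overlap unconstrained; disjoint assignment is used),
    the remaining annotated genes carry only near-miss decoy terms, and the
    rest are unannotated.
    """
    records: list[GeneRecord] = []
    for gene_set in DEFAULT_SET_ORDER:
        n_total, n_annotated, n_mt, n_cp = TABLE1_COUNTS[gene_set]
        prefix = _SET_PREFIX[gene_set]
        for i in range(n_total):
            annotated = i < n_annotated
            if i < n_mt:
                terms = frozenset({DEFAULT_TARGET_TERMS["N-mt"], "GO:0009508"})
            elif i < n_mt + n_cp:
                terms = frozenset({DEFAULT_TARGET_TERMS["N-cp"], "GO:0005740"})
            elif annotated:
                # annotated but in neither category; near-miss decoys only
                terms = frozenset({"GO:0005740", "GO:0008150"})
            else:
                terms = frozenset()
            records.append(
                GeneRecord(
                    gene_id=f"{prefix}{i:06d}",
                    set_label=gene_set,
                    annotated=annotated,
                    go_terms=terms,
                )
            )
    return records


def write_true_parameters(config: SyntheticConfig, path: str | Path) -> None:
    """Sidecar JSON of the generating parameters next to a written table."""
    Path(path).write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
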