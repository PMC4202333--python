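"""Per-gene GO annotation tables: reading, validation, and category counting.

The unit of data is a :class:`GeneRecord` — one transcript/gene with its
chromosomal gene-set label (autosomal, X-linked with a retained Y allele, or
X-hemizygous), whether functional annotation succeeded, and the set of GO
identifiers assigned to it. Tables arrive as tab-delimited exports in the
style of a Blast2GO annotation run, with the GO identifiers packed into one
``;``-separated column.

Downstream statistics only ever consume the :class:`CountSummary` produced
here: per gene set, the total number of genes, the number with any
annotation, and the number carrying each target cellular-component term
(by default GO:0005739 "mitochondrion" for N-mt genes and GO:0009507
"chloroplast" for N-cp genes). Matching is exact identifier membership —
no propagation to ontology ancestors or descendants — since Blast2GO-style
annotation sets conventionally already include the cellular-component
assignment itself.
"""

from __future__ import annotations

import csv
import dataclasses
import enum
import re
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TableFormatError, ValidationError

__all__ = [
    "GO_MITOCHONDRION",
    "GO_CHLOROPLAST",
    "DEFAULT_TARGET_TERMS",
    "GeneSet",
    "DEFAULT_SET_ORDER",
    "GeneRecord",
    "CountSummary",
    "read_annotation_table",
    "write_annotation_table",
    "assign_category_flags",
    "summarize_counts",
]

#: GO cellular-component term for "mitochondrion".
GO_MITOCHONDRION = "GO:0005739"
#: GO cellular-component term for "chloroplast".
GO_CHLOROPLAST = "GO:0009507"

#: Default analysis categories: nuclear-mitochondrial and nuclear-chloroplast.
DEFAULT_TARGET_TERMS: Mapping[str, str] = {
    "N-mt": GO_MITOCHONDRION,
    "N-cp": GO_CHLOROPLAST,
}

_GO_PATTERN = re.compile(r"^GO:\d{7}$")

REQUIRED_COLUMNS = ("gene_id", "set_label", "annotated", "go_terms")

_TRUE_STRINGS = {"true", "t", "1", "yes", "y"}
_FALSE_STRINGS = {"false", "f", "0", "no", "n", ""}


class GeneSet(enum.Enum):
    """The three chromosomal gene sets under comparison."""

    AUTOSOMAL = "autosomal"
    X_LINKED = "X-linked"
    X_HEMIZYGOUS = "X-hemizygous"

    @classmethod
    def parse(cls, label: str) -> "GeneSet":
        """Parse a gene-set label, tolerating case and ``_``/`` `` separators."""
        norm = label.strip().lower().replace("_", "-").replace(" ", "-")
        aliases = {
            "autosomal": cls.AUTOSOMAL,
            "autosome": cls.AUTOSOMAL,
            "a": cls.AUTOSOMAL,
            "x-linked": cls.X_LINKED,
            "xlinked": cls.X_LINKED,
            "x": cls.X_LINKED,
            "x-hemizygous": cls.X_HEMIZYGOUS,
            "hemizygous": cls.X_HEMIZYGOUS,
            "x-hemi": cls.X_HEMIZYGOUS,
        }
        try:
            return aliases[norm]
        except KeyError:
            raise ValidationError(f"unrecognized gene-set label: {label!r}") from None


#: Column order used throughout reports (matches the study's table layout).
DEFAULT_SET_ORDER: tuple[GeneSet, ...] = (
    GeneSet.AUTOSOMAL,
    GeneSet.X_LINKED,
    GeneSet.X_HEMIZYGOUS,
)


def _validate_go_term(term: str) -> None:
    if not _GO_PATTERN.match(term):
        raise ValidationError(
            f"malformed GO identifier {term!r}; expected 'GO:' plus 7 digits"
        )


@dataclasses.dataclass(frozen=True)
class GeneRecord:
    """One gene: identifier, gene-set label, annotation status, GO terms.

    Invariants enforced at construction: non-empty ``gene_id``, canonical
    ``GO:NNNNNNN`` identifiers, and ``go_terms`` empty unless ``annotated``.
    """

    gene_id: str
    set_label: GeneSet
    annotated: bool
    go_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if not isinstance(self.set_label, GeneSet):
            object.__setattr__(self, "set_label", GeneSet.parse(str(self.set_label)))
        if not isinstance(self.go_terms, frozenset):
            object.__setattr__(self, "go_terms", frozenset(self.go_terms))
        for term in self.go_terms:
            _validate_go_term(term)
        if self.go_terms and not self.annotated:
            raise ValidationError(
                f"gene {self.gene_id!r} carries GO terms but annotated is False"
            )


def read_annotation_table(
    path: str | Path,
    *,
    delimiter: str = "\t",
    go_separator: str = ";",
) -> list[GeneRecord]:
    """Read a per-gene annotation table into records, preserving input order.

    The file must be a delimited text table whose header contains at least
    the columns ``gene_id``, ``set_label``, ``annotated`` and ``go_terms``
    (extra columns are ignored). The GO column packs zero or more GO
    identifiers separated by *go_separator*; an empty GO column with
    ``annotated`` true means annotation succeeded but neither target term
    (nor any other) was recorded.

    Raises
    ------
    TableFormatError
        If a required column is missing from the header.
    ValidationError
        On duplicate gene identifiers (all duplicates listed) or an
        unrecognized gene-set label (with its row number).
    """
    path = Path(path)
    records: list[GeneRecord] = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise TableFormatError(f"{path}: empty file, expected a header line")
        header = [h.strip() for h in header]
        for column in REQUIRED_COLUMNS:
            if column not in header:
                raise TableFormatError(f"{path}: missing required column {column!r}")
        idx = {column: header.index(column) for column in REQUIRED_COLUMNS}
        for row_number, row in enumerate(reader, start=2):
            if not row or all(not field.strip() for field in row):
                continue
            try:
                label = GeneSet.parse(row[idx["set_label"]])
            except ValidationError as exc:
                raise ValidationError(f"{path}: row {row_number}: {exc}") from None
            annotated_raw = row[idx["annotated"]].strip().lower()
            if annotated_raw in _TRUE_STRINGS:
                annotated = True
            elif annotated_raw in _FALSE_STRINGS:
                annotated = False
            else:
                raise ValidationError(
                    f"{path}: row {row_number}: cannot parse annotated flag "
                    f"{row[idx['annotated']]!r}"
                )
            go_field = row[idx["go_terms"]].strip()
            terms = frozenset(
                t.strip() for t in go_field.split(go_separator) if t.strip()
            )
            records.append(
                GeneRecord(
                    gene_id=row[idx["gene_id"]].strip(),
                    set_label=label,
                    annotated=annotated,
                    go_terms=terms,
                )
            )
    duplicates = [g for g, n in Counter(r.gene_id for r in records).items() if n > 1]
    if duplicates:
        raise ValidationError(
            f"{path}: duplicate gene_id values: {sorted(duplicates)}"
        )
    return records


def write_annotation_table(
    records: Iterable[GeneRecord],
    path: str | Path,
    *,
    delimiter: str = "\t",
    go_separator: str = ";",
) -> None:
    """Write records as a delimited table readable by :func:`read_annotation_table`.

    GO terms are written in sorted order so output is deterministic.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter=delimiter, lineterminator="\n")
        writer.writerow(REQUIRED_COLUMNS)
        for record in records:
            writer.writerow(
                [
                    record.gene_id,
                    record.set_label.value,
                    "true" if record.annotated else "false",
                    go_separator.join(sorted(record.go_terms)),
                ]
            )


def assign_category_flags(
    records: Sequence[GeneRecord],
    target_terms: Mapping[str, str] | None = None,
) -> dict[str, np.ndarray]:
    """Flag each gene for each category by exact GO-identifier membership.

    Returns one boolean array per category, aligned with *records*. A gene is
    in a category iff that category's GO identifier is literally a member of
    its ``go_terms`` (so near-miss identifiers such as GO:0005740 never
    match, and unannotated genes are never flagged).
    """
    if target_terms is None:
        target_terms = DEFAULT_TARGET_TERMS
    for category, term in target_terms.items():
        if not isinstance(term, str):
            raise ValidationError(f"target term for {category!r} must be a string")
        _validate_go_term(term)
    return {
        category: np.fromiter(
            (term in record.go_terms for record in records),
            dtype=bool,
            count=len(records),
        )
        for category, term in target_terms.items()
    }


@dataclasses.dataclass(frozen=True)
class CountSummary:
    """Gene counts per set: total, annotated, and per-category flagged.

    This is the complete sufficient summary for the enrichment statistics:
    everything downstream (pooled proportions, expected counts, exact tests)
    is a function of these counts alone.
    """

    n_total: dict[GeneSet, int]
    n_annotated: dict[GeneSet, int]
    category_counts: dict[str, dict[GeneSet, int]]

    def __post_init__(self) -> None:
        for gene_set in self.sets:
            total = self.n_total[gene_set]
            annotated = self.n_annotated[gene_set]
            if not 0 <= annotated <= total:
                raise ValidationError(
                    f"{gene_set.value}: annotated count {annotated} outside "
                    f"[0, {total}]"
                )
            for category, counts in self.category_counts.items():
                flagged = counts[gene_set]
                if not 0 <= flagged <= annotated:
                    raise ValidationError(
                        f"{gene_set.value}/{category}: flagged count {flagged} "
                        f"outside [0, {annotated}]"
                    )

    @property
    def sets(self) -> tuple[GeneSet, ...]:
        return tuple(self.n_total)

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.category_counts)

    @property
    def total_genes(self) -> int:
        return sum(self.n_total.values())

    @property
    def total_annotated(self) -> int:
        return sum(self.n_annotated.values())

    def category_total(self, category: str) -> int:
        return sum(self.category_counts[category].values())

    # Convenience accessors mirroring the two default categories.
    @property
    def n_mt(self) -> tuple[int, ...]:
        return tuple(self.category_counts["N-mt"][s] for s in self.sets)

    @property
    def n_cp(self) -> tuple[int, ...]:
        return tuple(self.category_counts["N-cp"][s] for s in self.sets)

    def __add__(self, other: "CountSummary") -> "CountSummary":
        if self.sets != other.sets or self.categories != other.categories:
            raise ValidationError("cannot add summaries with different structure")
        return CountSummary(
            n_total={s: self.n_total[s] + other.n_total[s] for s in self.sets},
            n_annotated={
                s: self.n_annotated[s] + other.n_annotated[s] for s in self.sets
            },
            category_counts={
                c: {
                    s: self.category_counts[c][s] + other.category_counts[c][s]
                    for s in self.sets
                }
                for c in self.categories
            },
        )

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame, rows = count kinds, columns = gene sets."""
        rows: dict[str, list[int]] = {
            "n_total": [self.n_total[s] for s in self.sets],
            "n_annotated": [self.n_annotated[s] for s in self.sets],
        }
        for category in self.categories:
            rows[f"n[{category}]"] = [
                self.category_counts[category][s] for s in self.sets
            ]
        return pd.DataFrame(rows, index=[s.value for s in self.sets]).T

    def to_dict(self) -> dict:
        """JSON-serializable representation (set labels as strings)."""
        return {
            "n_total": {s.value: self.n_total[s] for s in self.sets},
            "n_annotated": {s.value: self.n_annotated[s] for s in self.sets},
            "category_counts": {
                c: {s.value: self.category_counts[c][s] for s in self.sets}
                for c in self.categories
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CountSummary":
        return cls(
            n_total={GeneSet(k): int(v) for k, v in data["n_total"].items()},
            n_annotated={
                GeneSet(k): int(v) for k, v in data["n_annotated"].items()
            },
            category_counts={
                c: {GeneSet(k): int(v) for k, v in counts.items()}
                for c, counts in data["category_counts"].items()
            },
        )


def summarize_counts(
    records: Sequence[GeneRecord],
    flags: Mapping[str, np.ndarray] | None = None,
    *,
    target_terms: Mapping[str, str] | None = None,
    sets: Sequence[GeneSet] = DEFAULT_SET_ORDER,
) -> CountSummary:
    """Tabulate total / annotated / per-category counts for each gene set.

    *flags* may be precomputed with :func:`assign_category_flags`; otherwise
    they are computed here from *target_terms* (default N-mt / N-cp). The
    result is independent of record order.
    """
    if len(records) == 0:
        raise ValidationError("cannot summarize an empty record collection")
    if flags is None:
        flags = assign_category_flags(records, target_terms)
    for category, arr in flags.items():
        if len(arr) != len(records):
            raise ValidationError(
                f"flags for {category!r} have length {len(arr)}, "
                f"expected {len(records)}"
            )
    set_index = {s: i for i, s in enumerate(sets)}
    try:
        labels = np.array([set_index[r.set_label] for r in records])
    except KeyError as exc:
        raise ValidationError(f"record with gene set {exc.args[0]} not in {sets}")
    annotated = np.fromiter(
        (r.annotated for r in records), dtype=bool, count=len(records)
    )
    n_total = {s: int((labels == i).sum()) for i, s in enumerate(sets)}
    n_annotated = {
        s: int((annotated & (labels == i)).sum()) for i, s in enumerate(sets)
    }
    category_counts = {
        category: {
            s: int((arr & (labels == i)).sum()) for i, s in enumerate(sets)
        }
        for category, arr in flags.items()
    }
    return CountSummary(
        n_total=n_total, n_annotated=n_annotated, category_counts=category_counts
    )
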