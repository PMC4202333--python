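"""End-to-end analysis: counts, enrichment ratios with CIs, exact tests, reports.

``run_analysis`` takes an annotation table (from disk, from the synthetic
generator, or the built-in deterministic fixture), computes the count
summary, the observed/expected ratio with a percentile-bootstrap CI for
every (gene set x category) pair, the 2x3 Freeman–Halton exact test per
category, and — because the hemizygous-specific comparisons are of separate
interest — pairwise 2x2 exact tests between every pair of gene sets.

All randomness flows from one integer seed through independent substreams,
so a report is bit-reproducible from its provenance block, and changing the
number of bootstrap replicates cannot alter counts, expected values, point
ratios, or p-values.

p-values are reported unadjusted (two planned tests, as in the analysis
this mirrors); a Bonferroni-adjusted column is included in the TSV output
as a clearly labelled extension.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np

from . import __version__
from .annotation import (
    CountSummary,
    DEFAULT_TARGET_TERMS,
    GeneRecord,
    GeneSet,
    assign_category_flags,
    read_annotation_table,
    summarize_counts,
)
from .contingency import (
    ContingencyTable2xK,
    ExactTestResult,
    chisq_pvalue,
    fisher_exact_2xk,
)
from .enrichment import RatioEstimate, bootstrap_ci
from .errors import ValidationError
from .simulate import SyntheticConfig, generate_annotation_table, generate_table1_fixture

__all__ = ["AnalysisReport", "run_analysis", "write_report", "read_report"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class AnalysisReport:
    """Complete results surface of one analysis run.

    ``ratio_estimates`` maps category -> gene set -> RatioEstimate;
    ``exact_tests`` maps category -> 2x3 (all gene sets) exact test;
    ``pairwise_tests`` maps category -> "setA|setB" -> 2x2 exact test;
    ``chisq_pvalues`` holds the asymptotic cross-check per category;
    ``provenance`` records everything needed to re-run bit-identically.
    """

    count_summary: CountSummary
    ratio_estimates: dict[str, dict[GeneSet, RatioEstimate]]
    exact_tests: dict[str, ExactTestResult]
    pairwise_tests: dict[str, dict[str, ExactTestResult]]
    chisq_pvalues: dict[str, float]
    provenance: dict

    def to_dict(self) -> dict:
        def ratio_dict(est: RatioEstimate) -> dict:
            return {
                "observed": est.observed,
                "expected": est.expected,
                "ratio": est.ratio,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n_boot": est.n_boot,
                "level": est.level,
            }

        def test_dict(res: ExactTestResult) -> dict:
            return {
                "p_value": res.p_value,
                "n_tables_enumerated": res.n_tables_enumerated,
                "observed_log_prob": res.observed_log_prob,
            }

        return {
            "count_summary": self.count_summary.to_dict(),
            "ratio_estimates": {
                c: {s.value: ratio_dict(e) for s, e in per_set.items()}
                for c, per_set in self.ratio_estimates.items()
            },
            "exact_tests": {c: test_dict(r) for c, r in self.exact_tests.items()},
            "pairwise_tests": {
                c: {pair: test_dict(r) for pair, r in per_pair.items()}
                for c, per_pair in self.pairwise_tests.items()
            },
            "chisq_pvalues": dict(self.chisq_pvalues),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "AnalysisReport":
        def ratio_est(d: Mapping) -> RatioEstimate:
            return RatioEstimate(
                observed=int(d["observed"]),
                expected=float(d["expected"]),
                ratio=float(d["ratio"]),
                ci_low=d["ci_low"],
                ci_high=d["ci_high"],
                n_boot=int(d["n_boot"]),
                level=float(d["level"]),
            )

        def test_res(d: Mapping) -> ExactTestResult:
            return ExactTestResult(
                p_value=float(d["p_value"]),
                n_tables_enumerated=int(d["n_tables_enumerated"]),
                observed_log_prob=float(d["observed_log_prob"]),
            )

        return cls(
            count_summary=CountSummary.from_dict(data["count_summary"]),
            ratio_estimates={
                c: {GeneSet(s): ratio_est(e) for s, e in per_set.items()}
                for c, per_set in data["ratio_estimates"].items()
            },
            exact_tests={
                c: test_res(r) for c, r in data["exact_tests"].items()
            },
            pairwise_tests={
                c: {pair: test_res(r) for pair, r in per_pair.items()}
                for c, per_pair in data["pairwise_tests"].items()
            },
            chisq_pvalues={
                c: float(p) for c, p in data["chisq_pvalues"].items()
            },
            provenance=dict(data["provenance"]),
        )

    def to_json(self) -> str:
        """Deterministic JSON encoding (sorted keys, fixed layout)."""
        return json.dumps(self.to_dict(), sort_keys=True, indent=2) + "\n"


def _resolve_records(
    records: Sequence[GeneRecord] | None,
    input_path: str | Path | None,
    synthetic_config: SyntheticConfig | None,
    fixture: str | None,
) -> tuple[list[GeneRecord], dict]:
    sources = [
        records is not None,
        input_path is not None,
        synthetic_config is not None,
        fixture is not None,
    ]
    if sum(sources) != 1:
        raise ValidationError(
            "exactly one of records / input_path / synthetic_config / fixture "
            "must be given"
        )
    if records is not None:
        return list(records), {"source": "records", "n_records": len(records)}
    if input_path is not None:
        return (
            read_annotation_table(input_path),
            {"source": "file", "input_path": str(input_path)},
        )
    if synthetic_config is not None:
        return (
            generate_annotation_table(synthetic_config),
            {"source": "synthetic", "config": synthetic_config.to_dict()},
        )
    if fixture != "table1":
        raise ValidationError(f"unknown fixture {fixture!r}; only 'table1'")
    return generate_table1_fixture(), {"source": "fixture", "fixture": "table1"}


def run_analysis(
    records: Sequence[GeneRecord] | None = None,
    *,
    input_path: str | Path | None = None,
    synthetic_config: SyntheticConfig | None = None,
    fixture: str | None = None,
    target_terms: Mapping[str, str] | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
    alpha: float = 0.05,
    pairwise: bool = True,
) -> AnalysisReport:
    """Run the full enrichment analysis on one annotation table.

    Exactly one input source must be supplied. Deterministic given *seed*;
    the bootstrap for each (category, gene set) pair uses an independent
    substream, so results do not depend on iteration order.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    if target_terms is None:
        target_terms = DEFAULT_TARGET_TERMS
    table_records, source_info = _resolve_records(
        records, input_path, synthetic_config, fixture
    )
    flags = assign_category_flags(table_records, target_terms)
    summary = summarize_counts(table_records, flags, target_terms=target_terms)
    logger.info(
        "analysing %d genes (%d annotated) across %d sets, categories %s",
        summary.total_genes,
        summary.total_annotated,
        len(summary.sets),
        list(target_terms),
    )

    categories = tuple(target_terms)
    seed_root = np.random.SeedSequence(seed)
    substreams = iter(seed_root.spawn(len(categories) * len(summary.sets)))

    ratio_estimates: dict[str, dict[GeneSet, RatioEstimate]] = {}
    exact_tests: dict[str, ExactTestResult] = {}
    pairwise_tests: dict[str, dict[str, ExactTestResult]] = {}
    chisq_pvalues: dict[str, float] = {}
    for category in categories:
        per_set: dict[GeneSet, RatioEstimate] = {}
        for gene_set in summary.sets:
            stream = next(substreams)
            per_set[gene_set] = bootstrap_ci(
                table_records,
                gene_set,
                category,
                n_boot=n_boot,
                seed=np.random.default_rng(stream),
                level=level,
                flags=flags,
            )
        ratio_estimates[category] = per_set

        table = ContingencyTable2xK.from_summary(summary, category)
        result = fisher_exact_2xk(table)
        exact_tests[category] = result
        chisq_pvalues[category] = chisq_pvalue(table)
        logger.info(
            "%s: exact 2x%d p=%.4f over %d tables",
            category,
            table.k,
            result.p_value,
            result.n_tables_enumerated,
        )
        if pairwise:
            per_pair: dict[str, ExactTestResult] = {}
            arr = table.array
            for i, j in itertools.combinations(range(len(summary.sets)), 2):
                sub = ContingencyTable2xK.from_rows(
                    (arr[0, i], arr[0, j]), (arr[1, i], arr[1, j])
                )
                key = f"{summary.sets[i].value}|{summary.sets[j].value}"
                per_pair[key] = fisher_exact_2xk(sub)
            pairwise_tests[category] = per_pair

    provenance = {
        **source_info,
        "seed": seed,
        "n_boot": n_boot,
        "level": level,
        "alpha": alpha,
        "target_terms": dict(target_terms),
        "version": __version__,
    }
    return AnalysisReport(
        count_summary=summary,
        ratio_estimates=ratio_estimates,
        exact_tests=exact_tests,
        pairwise_tests=pairwise_tests,
        chisq_pvalues=chisq_pvalues,
        provenance=provenance,
    )


def write_report(
    report: AnalysisReport,
    out_dir: str | Path,
    formats: Sequence[str] = ("tsv", "json"),
    *,
    plot_data: bool = True,
    plot: bool = False,
) -> dict[str, Path]:
    """Write the report to *out_dir*; returns the paths written.

    Always available: ``report.json`` (full fidelity) and the TSV trio
    ``counts.tsv`` / ``ratios.tsv`` / ``tests.tsv``. ``plot_data.tsv``
    mirrors a forest plot: one row per (gene set, category) with the ratio
    and CI bounds, reference value 1 = no over/underrepresentation. With
    ``plot=True`` a PNG of that forest plot is rendered via matplotlib.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    summary = report.count_summary
    n_tests = len(report.exact_tests)

    if "json" in formats:
        path = out_dir / "report.json"
        path.write_text(report.to_json(), encoding="utf-8")
        written["json"] = path

    if "tsv" in formats:
        counts_path = out_dir / "counts.tsv"
        summary.to_frame().to_csv(counts_path, sep="\t")
        written["counts"] = counts_path

        ratios_path = out_dir / "ratios.tsv"
        with ratios_path.open("w", encoding="utf-8") as handle:
            handle.write(
                "category\tgene_set\tobserved\texpected\tratio\t"
                "ci_low\tci_high\tn_boot\tlevel\n"
            )
            for category, per_set in report.ratio_estimates.items():
                for gene_set, est in per_set.items():
                    handle.write(
                        f"{category}\t{gene_set.value}\t{est.observed}\t"
                        f"{est.expected!r}\t{est.ratio!r}\t{est.ci_low!r}\t"
                        f"{est.ci_high!r}\t{est.n_boot}\t{est.level}\n"
                    )
        written["ratios"] = ratios_path

        tests_path = out_dir / "tests.tsv"
        with tests_path.open("w", encoding="utf-8") as handle:
            # p_bonferroni is an extension: the source analysis reports
            # unadjusted p-values for its two planned tests.
            handle.write(
                "category\tcomparison\tp_value\tp_bonferroni\t"
                "n_tables_enumerated\tchisq_p\n"
            )
            for category, result in report.exact_tests.items():
                adjusted = min(1.0, result.p_value * n_tests)
                handle.write(
                    f"{category}\tall_sets_2x{len(summary.sets)}\t"
                    f"{result.p_value!r}\t{adjusted!r}\t"
                    f"{result.n_tables_enumerated}\t"
                    f"{report.chisq_pvalues[category]!r}\n"
                )
            for category, per_pair in report.pairwise_tests.items():
                for pair, result in per_pair.items():
                    handle.write(
                        f"{category}\t{pair}\t{result.p_value!r}\t\t"
                        f"{result.n_tables_enumerated}\t\n"
                    )
        written["tests"] = tests_path

    if plot_data:
        plot_path = out_dir / "plot_data.tsv"
        with plot_path.open("w", encoding="utf-8") as handle:
            handle.write("gene_set\tcategory\tratio\tci_low\tci_high\n")
            for category, per_set in report.ratio_estimates.items():
                for gene_set, est in per_set.items():
                    handle.write(
                        f"{gene_set.value}\t{category}\t{est.ratio!r}\t"
                        f"{est.ci_low!r}\t{est.ci_high!r}\n"
                    )
        written["plot_data"] = plot_path

    if plot:
        written["plot"] = _render_forest_plot(report, out_dir / "ratios.png")
    return written


def _render_forest_plot(report: AnalysisReport, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    y = 0
    ticks, labels = [], []
    for category, per_set in report.ratio_estimates.items():
        for gene_set, est in per_set.items():
            ax.errorbar(
                est.ratio,
                y,
                xerr=[[est.ratio - est.ci_low], [est.ci_high - est.ratio]],
                fmt="o",
                color="black",
                capsize=3,
            )
            ticks.append(y)
            labels.append(f"{category} {gene_set.value}")
            y += 1
    ax.axvline(1.0, linestyle=":", color="grey")
    ax.set_yticks(ticks, labels)
    ax.set_xlabel("observed / expected ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def read_report(path: str | Path) -> AnalysisReport:
    """Read back a ``report.json`` written by :func:`write_report`."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return AnalysisReport.from_dict(data)
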