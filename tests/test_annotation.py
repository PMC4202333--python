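"""Annotation-table parsing, validation, and count summarisation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cytonuclear as cn
from cytonuclear.annotation import DEFAULT_SET_ORDER

MT = cn.GO_MITOCHONDRION
CP = cn.GO_CHLOROPLAST


def _write(tmp_path, text, name="table.tsv"):
    path = tmp_path / name
    path.write_text(text, encoding="utf-8")
    return path


class TestReadAnnotationTable:
    def test_three_row_identity(self, tmp_path):
        path = _write(
            tmp_path,
            "gene_id\tset_label\tannotated\tgo_terms\n"
            "g1\tautosomal\ttrue\tGO:0005739\n"
            "g2\tX-linked\ttrue\t\n"
            "g3\tX-hemizygous\tfalse\t\n",
        )
        records = cn.read_annotation_table(path)
        assert [r.set_label for r in records] == list(DEFAULT_SET_ORDER)
        assert [r.gene_id for r in records] == ["g1", "g2", "g3"]
        assert records[1].annotated and not records[1].go_terms
        assert not records[2].annotated

    def test_go_field_with_multiple_terms(self, tmp_path):
        path = _write(
            tmp_path,
            "gene_id\tset_label\tannotated\tgo_terms\n"
            f"g1\tautosomal\ttrue\t{MT};{CP}\n",
        )
        (record,) = cn.read_annotation_table(path)
        assert record.go_terms == frozenset({MT, CP})

    def test_missing_column_names_the_column(self, tmp_path):
        path = _write(
            tmp_path, "gene_id\tset_label\tannotated\ng1\tautosomal\ttrue\n"
        )
        with pytest.raises(cn.TableFormatError, match="go_terms"):
            cn.read_annotation_table(path)

    def test_duplicate_gene_ids_are_listed(self, tmp_path):
        path = _write(
            tmp_path,
            "gene_id\tset_label\tannotated\tgo_terms\n"
            "g1\tautosomal\ttrue\t\n"
            "g1\tX-linked\ttrue\t\n",
        )
        with pytest.raises(cn.ValidationError, match="g1"):
            cn.read_annotation_table(path)

    def test_bad_set_label_reports_row_number(self, tmp_path):
        path = _write(
            tmp_path,
            "gene_id\tset_label\tannotated\tgo_terms\n"
            "g1\tautosomal\ttrue\t\n"
            "g2\tY-linked\ttrue\t\n",
        )
        with pytest.raises(cn.ValidationError, match="row 3"):
            cn.read_annotation_table(path)

    def test_custom_go_separator(self, tmp_path):
        path = _write(
            tmp_path,
            "gene_id\tset_label\tannotated\tgo_terms\n"
            f"g1\tautosomal\ttrue\t{MT},{CP}\n",
        )
        (record,) = cn.read_annotation_table(path, go_separator=",")
        assert record.go_terms == frozenset({MT, CP})


class TestGeneRecordValidation:
    def test_terms_without_annotation_rejected(self):
        with pytest.raises(cn.ValidationError):
            cn.GeneRecord("g1", cn.GeneSet.AUTOSOMAL, False, frozenset({MT}))

    @pytest.mark.parametrize("bad", ["GO:123", "go:0005739", "0005739", "GO:12345678"])
    def test_malformed_go_identifier_rejected(self, bad):
        with pytest.raises(cn.ValidationError):
            cn.GeneRecord("g1", cn.GeneSet.AUTOSOMAL, True, frozenset({bad}))

    def test_empty_gene_id_rejected(self):
        with pytest.raises(cn.ValidationError):
            cn.GeneRecord("", cn.GeneSet.AUTOSOMAL, True)


class TestCategoryFlags:
    def test_exact_membership_only(self):
        records = [
            cn.GeneRecord("g1", cn.GeneSet.AUTOSOMAL, True, frozenset({MT})),
            cn.GeneRecord("g2", cn.GeneSet.AUTOSOMAL, True, frozenset()),
            # near-miss identifiers one digit away must not match
            cn.GeneRecord(
                "g3", cn.GeneSet.AUTOSOMAL, True,
                frozenset({"GO:0005740", "GO:0009508"}),
            ),
        ]
        flags = cn.assign_category_flags(records)
        assert flags["N-mt"].tolist() == [True, False, False]
        assert flags["N-cp"].tolist() == [False, False, False]

    def test_malformed_target_term_rejected(self):
        records = [cn.GeneRecord("g1", cn.GeneSet.AUTOSOMAL, True)]
        with pytest.raises(cn.ValidationError):
            cn.assign_category_flags(records, {"N-mt": "mitochondrion"})


class TestSummarizeCounts:
    def test_single_gene_no_target_terms(self):
        records = [
            cn.GeneRecord("g1", cn.GeneSet.AUTOSOMAL, True, frozenset({"GO:0008150"}))
        ]
        summary = cn.summarize_counts(records)
        assert summary.n_total[cn.GeneSet.AUTOSOMAL] == 1
        assert summary.n_annotated[cn.GeneSet.AUTOSOMAL] == 1
        assert summary.n_mt == (0, 0, 0)
        assert summary.n_cp == (0, 0, 0)

    def test_empty_input_rejected(self):
        with pytest.raises(cn.ValidationError):
            cn.summarize_counts([])

    def test_permutation_invariance(self, table1_records):
        rng = np.random.default_rng(0)
        shuffled = [table1_records[i] for i in rng.permutation(len(table1_records))]
        assert cn.summarize_counts(shuffled) == cn.summarize_counts(table1_records)

    def test_concatenation_additivity(self, table1_records):
        half = len(table1_records) // 2
        first, second = table1_records[:half], table1_records[half:]
        combined = cn.summarize_counts(first) + cn.summarize_counts(second)
        assert combined == cn.summarize_counts(table1_records)

    def test_per_category_counts_bounded_by_annotated(self, table1_summary):
        for category in table1_summary.categories:
            for gene_set in table1_summary.sets:
                assert (
                    0
                    <= table1_summary.category_counts[category][gene_set]
                    <= table1_summary.n_annotated[gene_set]
                    <= table1_summary.n_total[gene_set]
                )


class TestTable1Fixture:
    """The deterministic fixture must reproduce every published count."""

    def test_marginal_totals(self, table1_summary):
        assert tuple(table1_summary.n_total.values()) == (1167, 624, 107)
        assert tuple(table1_summary.n_annotated.values()) == (1073, 567, 95)

    def test_category_counts(self, table1_summary):
        assert table1_summary.n_mt == (194, 94, 13)
        assert table1_summary.n_cp == (222, 102, 22)

    def test_fixture_roundtrips_through_tsv(self, table1_records, tmp_path):
        path = tmp_path / "rumex_table1.tsv"
        cn.write_annotation_table(table1_records, path)
        assert cn.read_annotation_table(path) == table1_records


go_terms_strategy = st.frozensets(
    st.from_regex(r"GO:[0-9]{7}", fullmatch=True), max_size=4
)


@st.composite
def gene_records(draw, index):
    annotated = draw(st.booleans())
    terms = draw(go_terms_strategy) if annotated else frozenset()
    return cn.GeneRecord(
        gene_id=f"gene{index}",
        set_label=draw(st.sampled_from(list(cn.GeneSet))),
        annotated=annotated,
        go_terms=terms,
    )


@st.composite
def record_tables(draw):
    n = draw(st.integers(min_value=1, max_value=30))
    return [draw(gene_records(i)) for i in range(n)]


@given(records=record_tables())
def test_write_read_roundtrip_is_identity(records, tmp_path_factory):
    path = tmp_path_factory.mktemp("roundtrip") / "table.tsv"
    cn.write_annotation_table(records, path)
    assert cn.read_annotation_table(path) == records
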