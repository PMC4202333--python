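"""Exact-test machinery: enumeration, probabilities, p-values."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import hypergeom

import cytonuclear as cn
from cytonuclear.contingency import ContingencyTable2xK


def two_sided_hypergeom_p(a, b, c, d, tol=1e-7):
    """Independent 2x2 oracle: direct sum over the single free cell."""
    r1, c1, n = a + b, a + c, a + b + c + d
    support = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    p_obs = hypergeom.pmf(a, n, c1, r1)
    return sum(
        p for x in support
        if (p := hypergeom.pmf(x, n, c1, r1)) <= p_obs * (1 + tol)
    )


class TestTableType:
    def test_margins(self):
        table = ContingencyTable2xK.from_rows((3, 1), (1, 3))
        assert table.row_totals == (4, 4)
        assert table.col_totals == (4, 4)
        assert table.grand_total == 8

    @pytest.mark.parametrize(
        "cells",
        [((1,), (2,)), ((1, -1), (0, 2)), ((1.5, 1), (1, 1))],
    )
    def test_invalid_tables_rejected(self, cells):
        with pytest.raises(cn.ValidationError):
            ContingencyTable2xK(cells)

    def test_from_summary_uses_annotated_denominators(self, table1_summary):
        table = ContingencyTable2xK.from_summary(table1_summary, "N-mt")
        assert table.cells == ((194, 94, 13), (879, 473, 82))
        table = ContingencyTable2xK.from_summary(table1_summary, "N-cp")
        assert table.cells == ((222, 102, 22), (851, 465, 73))


class TestLogTableProbability:
    def test_2x2_closed_form(self):
        # C(4,3)*C(4,1)/C(8,4) = 16/70
        table = ContingencyTable2xK.from_rows((3, 1), (1, 3))
        assert cn.log_table_probability(table) == pytest.approx(
            math.log(16 / 70), abs=1e-12
        )

    def test_zero_column_reduces(self):
        full = ContingencyTable2xK.from_rows((3, 1, 0), (1, 3, 0))
        reduced = ContingencyTable2xK.from_rows((3, 1), (1, 3))
        assert cn.log_table_probability(full) == pytest.approx(
            cn.log_table_probability(reduced), abs=1e-12
        )

    @given(
        cells=st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=8),
                st.integers(min_value=0, max_value=8),
            ),
            min_size=2,
            max_size=4,
        )
    )
    def test_probabilities_normalize(self, cells):
        """Sum of exp(log p) over all margin-consistent tables equals one."""
        arr = np.array(cells).T  # 2 x K
        rows, cols = arr.sum(axis=1), arr.sum(axis=0)
        total = sum(
            math.exp(cn.log_table_probability(t))
            for t in cn.enumerate_tables(rows, cols)
        )
        assert total == pytest.approx(1.0, abs=1e-9)


class TestEnumerateTables:
    def test_small_margin_count(self):
        tables = list(cn.enumerate_tables((2, 2), (2, 2)))
        assert len(tables) == 3
        assert len({t.cells for t in tables}) == 3

    def test_zero_row_total_single_table(self):
        tables = list(cn.enumerate_tables((0, 4), (2, 2)))
        assert len(tables) == 1
        assert tables[0].cells == ((0, 0), (2, 2))

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(cn.ValidationError):
            list(cn.enumerate_tables((2, 2), (3, 2)))

    def test_matches_brute_force_double_loop(self):
        rows, cols = (7, 11), (6, 8, 4)
        brute = [
            (a, b, rows[0] - a - b)
            for a in range(cols[0] + 1)
            for b in range(cols[1] + 1)
            if 0 <= rows[0] - a - b <= cols[2]
        ]
        enumerated = [t.cells[0] for t in cn.enumerate_tables(rows, cols)]
        assert sorted(enumerated) == sorted(brute)
        for t in cn.enumerate_tables(rows, cols):
            assert t.row_totals == rows
            assert t.col_totals == cols

    def test_study_scale_margins_all_consistent(self):
        count = 0
        for t in cn.enumerate_tables((301, 1434), (1073, 567, 95)):
            count += 1
        # brute-force count over the two free cells
        brute = sum(
            1
            for a in range(min(301, 1073) + 1)
            for b in range(min(301 - a, 567) + 1)
            if 301 - a - b <= 95
        )
        assert count == brute


class TestFisherExact2xK:
    def test_2x2_example(self):
        result = cn.fisher_exact_2xk(ContingencyTable2xK.from_rows((3, 1), (1, 3)))
        # two-sided hypergeometric sum: 2 * (16 + 1) / 70
        assert result.p_value == pytest.approx(34 / 70, abs=1e-12)
        assert round(result.p_value, 4) == 0.4857

    def test_homogeneous_table_p_one(self):
        result = cn.fisher_exact_2xk(ContingencyTable2xK.from_rows((5, 5), (5, 5)))
        assert result.p_value == pytest.approx(1.0, abs=1e-9)

    def test_p_at_least_observed_probability(self, table1_summary):
        table = ContingencyTable2xK.from_summary(table1_summary, "N-mt")
        result = cn.fisher_exact_2xk(table)
        assert result.p_value >= math.exp(result.observed_log_prob)

    def test_study_tables_match_independent_enumeration(self, table1_summary):
        """The 2x3 exact p-values, frozen from an independent full-enumeration
        oracle (cross-checked against R fisher.test exact values)."""
        p_mt = cn.fisher_exact_2xk(
            ContingencyTable2xK.from_summary(table1_summary, "N-mt")
        ).p_value
        p_cp = cn.fisher_exact_2xk(
            ContingencyTable2xK.from_summary(table1_summary, "N-cp")
        ).p_value
        assert p_mt == pytest.approx(0.4973926169, abs=1e-9)
        assert p_cp == pytest.approx(0.3075503817, abs=1e-9)

    def test_matches_2x2_hypergeometric_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 16, size=4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            table = ContingencyTable2xK.from_rows((a, b), (c, d))
            expected = two_sided_hypergeom_p(int(a), int(b), int(c), int(d))
            assert cn.fisher_exact_2xk(table).p_value == pytest.approx(
                expected, abs=1e-10
            )

    def test_enumeration_cap_raises(self, table1_summary):
        table = ContingencyTable2xK.from_summary(table1_summary, "N-mt")
        with pytest.raises(cn.EnumerationLimitError, match="chisq"):
            cn.fisher_exact_2xk(table, max_tables=100)

    def test_null_rejection_rate_conservative(self, table1_summary):
        """Conditional null: fixed-margin hypergeometric draws; the exact
        test rejects at 0.05 in at most 6% of 2,000 tables."""
        table = ContingencyTable2xK.from_summary(table1_summary, "N-mt")
        rng = np.random.default_rng(7)
        tables = cn.sample_null_tables(
            table.row_totals, table.col_totals, 2000, rng
        )
        rejections = sum(
            cn.fisher_exact_2xk(t).p_value <= 0.05 for t in tables
        )
        assert rejections / 2000 <= 0.06


class TestChisqPvalue:
    def test_study_table_statistic(self, table1_summary):
        # hand computation of sum (O-E)^2/E gives 2.345 on 2 df
        table = ContingencyTable2xK.from_summary(table1_summary, "N-cp")
        assert cn.chisq_pvalue(table) == pytest.approx(0.30958, abs=1e-4)

    def test_proportional_table_p_one(self):
        table = ContingencyTable2xK.from_rows((10, 20), (20, 40))
        assert cn.chisq_pvalue(table) == pytest.approx(1.0, abs=1e-12)

    def test_zero_expected_rejected(self):
        with pytest.raises(cn.ValidationError):
            cn.chisq_pvalue(ContingencyTable2xK.from_rows((0, 5), (0, 5)))

    def test_agrees_with_exact_for_large_expected(self):
        """Asymptotics: |exact - chisq| < 0.05 when expected counts >= 15."""
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 10:
            cells = rng.integers(15, 120, size=(2, 3))
            table = ContingencyTable2xK(tuple(map(tuple, cells)))
            expected = (
                np.outer(table.row_totals, table.col_totals) / table.grand_total
            )
            if expected.min() < 15:
                continue
            diff = abs(
                cn.fisher_exact_2xk(table).p_value - cn.chisq_pvalue(table)
            )
            assert diff < 0.05
            checked += 1
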