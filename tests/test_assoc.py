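import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tipscan.assoc import (
    AssociationResult,
    ContingencyTable,
    associate_all,
    chi_square,
    contingency_coefficient,
    decide,
    expected_frequencies,
    make_table,
    per_chromosome_counts,
)
from tipscan.errors import ConfigurationError, DegenerateTableError, LabelingError
from tipscan.simulate import simulate_presence_matrix


def shortcut_chi2(O):
    """2x2 closed form: n (ad - bc)^2 / (n1. n2. n.1 n.2)."""
    a, b = O[0]
    c, d = O[1]
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


tables = st.tuples(*(st.integers(0, 60) for _ in range(4))).map(
    lambda t: ContingencyTable(np.array(t).reshape(2, 2))
)
nondegenerate_tables = tables.filter(lambda t: not t.degenerate)


class TestMakeTable:
    def _matrix(self):
        return simulate_presence_matrix(4, 4, [1.0], [0.0], seed=0)

    def test_perfect_separation_counts(self):
        table = make_table(self._matrix(), ("chr1", 0, 10_000))
        assert table.O.tolist() == [[4, 0], [0, 4]]

    def test_absent_window_has_zero_presence_row(self):
        matrix = simulate_presence_matrix(3, 3, [0.0], [0.0], seed=0)
        table = make_table(matrix, ("chr1", 0, 10_000))
        assert table.O[1].tolist() == [0, 0]
        assert table.degenerate

    def test_joint_row_permutation_leaves_table_unchanged(self, rng):
        matrix = simulate_presence_matrix(5, 5, [0.6], [0.2], seed=1)
        perm = rng.permutation(matrix.n)
        from tipscan.cohort import TipMatrix

        shuffled = TipMatrix(
            [matrix.samples[i] for i in perm],
            matrix.windows,
            matrix.data[perm],
            matrix.labels,
        )
        assert (make_table(shuffled, matrix.windows[0]).O == make_table(matrix, matrix.windows[0]).O).all()


class TestExpectedFrequencies:
    def test_uniform_margins(self):
        e = expected_frequencies(ContingencyTable(np.array([[20, 5], [5, 20]])))
        assert np.allclose(e, 12.5)

    def test_proportional_rows_reproduce_observed(self):
        O = np.array([[2, 8], [10, 40]])
        assert np.allclose(expected_frequencies(ContingencyTable(O)), O)

    @given(nondegenerate_tables)
    def test_conservation_of_grand_total(self, table):
        assert expected_frequencies(table).sum() == pytest.approx(table.n)

    def test_empty_table_raises(self):
        with pytest.raises(DegenerateTableError):
            expected_frequencies(ContingencyTable(np.zeros((2, 2), dtype=int)))


class TestChiSquare:
    def test_uniform_table_has_zero_statistic(self):
        out = chi_square(ContingencyTable(np.full((2, 2), 10)))
        assert out.chi2 == 0.0 and not out.yates_used

    def test_worked_value_without_correction(self):
        out = chi_square(ContingencyTable(np.array([[20, 5], [5, 20]])))
        assert out.chi2 == pytest.approx(18.0, abs=1e-12)
        assert not out.yates_used

    def test_yates_modes_on_expected_equal_observed(self):
        table = ContingencyTable(np.array([[1, 9], [9, 81]]))
        floored = chi_square(table, "floored")
        literal = chi_square(table, "literal")
        assert floored.yates_used and literal.yates_used
        assert floored.chi2 == 0.0
        assert literal.chi2 == pytest.approx(0.308641975, abs=1e-6)

    @given(nondegenerate_tables)
    def test_matches_shortcut_formula_when_no_correction(self, table):
        out = chi_square(table)
        if not out.yates_used:
            assert out.chi2 == pytest.approx(shortcut_chi2(table.O), abs=1e-9)

    @given(nondegenerate_tables)
    def test_yates_triggered_iff_min_expected_below_five(self, table):
        assert chi_square(table).yates_used == (expected_frequencies(table).min() < 5)

    @given(nondegenerate_tables)
    def test_simultaneous_row_and_column_swap_symmetry(self, table):
        swapped = ContingencyTable(table.O[::-1, ::-1].copy())
        assert chi_square(swapped).chi2 == pytest.approx(chi_square(table).chi2)

    def test_zero_margin_reports_degenerate_without_raising(self):
        out = chi_square(ContingencyTable(np.array([[5, 5], [0, 0]])))
        assert out.degenerate and out.chi2 == 0.0


class TestDecide:
    def test_worked_critical_value_at_five_percent(self):
        critical, significant, p = decide(18.0, alpha=0.05, df=1)
        assert critical == pytest.approx(3.841, abs=1e-3)
        assert significant and p < 0.05

    def test_zero_statistic_never_significant(self):
        for alpha in (0.5, 0.05, 0.001):
            _, significant, _ = decide(0.0, alpha=alpha)
            assert not significant

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ConfigurationError):
            decide(1.0, alpha=1.5)

    @given(nondegenerate_tables, st.sampled_from([0.1, 0.05, 0.01]))
    def test_decision_agrees_with_p_value_threshold(self, table, alpha):
        chi2 = chi_square(table).chi2
        _, significant, p = decide(chi2, alpha=alpha)
        assert significant == (p <= alpha)


class TestContingencyCoefficient:
    def test_zero_statistic_in_both_modes(self):
        assert contingency_coefficient(0.0, 10) == 0.0
        assert contingency_coefficient(0.0, 10, "literal") == 0.0

    def test_worked_values(self):
        assert contingency_coefficient(18.0, 50) == pytest.approx(0.5145, abs=1e-4)
        assert contingency_coefficient(18.0, 50, "literal") == pytest.approx(0.2647, abs=1e-4)

    def test_large_statistic_approaches_one(self):
        assert contingency_coefficient(1e12, 50) == pytest.approx(1.0, abs=1e-6)

    def test_zero_n_raises(self):
        with pytest.raises(DegenerateTableError):
            contingency_coefficient(1.0, 0)


class TestAssociateAll:
    def test_perfectly_separating_window_is_significant(self):
        matrix = simulate_presence_matrix(15, 15, [1.0], [0.0], seed=0)
        (result,) = associate_all(matrix)
        # shortcut gives chi2 = 30 before any correction; min e = 7.5, no Yates
        assert not result.yates_used
        assert result.chi2 == pytest.approx(30.0)
        assert result.significant

    def test_bonferroni_significant_set_is_subset_of_uncorrected(self):
        matrix = simulate_presence_matrix(20, 20, [0.7] * 30, [0.25] * 30, seed=3)
        plain = {r.window for r in associate_all(matrix) if r.significant}
        strict = {
            r.window
            for r in associate_all(matrix, correction="bonferroni")
            if r.significant
        }
        assert strict <= plain

    def test_bh_significant_set_is_subset_of_uncorrected(self):
        matrix = simulate_presence_matrix(20, 20, [0.7] * 30, [0.25] * 30, seed=4)
        plain = {r.window for r in associate_all(matrix) if r.significant}
        bh = {r.window for r in associate_all(matrix, correction="bh") if r.significant}
        assert bh <= plain

    def test_single_class_cohort_raises(self):
        matrix = simulate_presence_matrix(5, 0, [0.5], [0.5], seed=0)
        with pytest.raises(LabelingError):
            associate_all(matrix)

    def test_per_chromosome_counts_group_significant_windows(self):
        results = []
        for chrom, sig in [("chr2", True), ("chr10", True), ("chr2", False)]:
            matrix = simulate_presence_matrix(10, 10, [1.0 if sig else 0.5],
                                              [0.0 if sig else 0.5], seed=1, chrom=chrom)
            results.extend(associate_all(matrix))
        counts = per_chromosome_counts(results)
        assert list(counts) == ["chr2", "chr10"]
        assert counts["chr2"] >= 1 and counts["chr10"] >= 1
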