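r"""Chi-square association between TIP presence and a binary condition.

For each TIP window j, a 2x2 contingency table crosses Y (window presence,
rows) with X (condition, columns) over the n cohort samples:

             X = 0      X = 1
    Y = 0    O_00       O_01
    Y = 1    O_10       O_11

Expected frequencies are e_ij = n_i. * n_.j / n and the test statistic is
chi^2 = sum_ij (O_ij - e_ij)^2 / e_ij with df = (r-1)(s-1) = 1. When the
smallest expected frequency falls below 5, Yates' continuity correction is
applied: chi^2 = sum_ij (|O_ij - e_ij| - 0.5)^2 / e_ij. In the default
``floored`` mode the corrected deviation |O - e| - 0.5 is clipped at zero,
so a table with O == e keeps chi^2 = 0; ``literal`` mode evaluates the
uncorrected textbook formula as written. Window j is declared associated
when chi^2 >= the upper-alpha quantile of chi^2_1.

Association strength is Pearson's contingency coefficient
C = sqrt(chi^2 / (n + chi^2)) (default ``sqrt`` mode); ``literal`` mode
omits the radical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Literal, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import TipMatrix, Window, window_key_str
from .errors import ConfigurationError, DegenerateTableError, LabelingError
from .io_formats import natural_key

YatesMode = Literal["floored", "literal"]
CMode = Literal["sqrt", "literal"]
Correction = Literal["none", "bonferroni", "bh"]

YATES_MIN_EXPECTED = 5.0  # smallest expected cell frequency before correction


@dataclass(slots=True)
class ContingencyTable:
    """2x2 observed frequencies, rows = Y (presence), cols = X (condition)."""

    O: np.ndarray

    def __post_init__(self) -> None:
        self.O = np.asarray(self.O, dtype=np.int64)
        if self.O.shape != (2, 2) or (self.O < 0).any():
            raise DegenerateTableError(
                f"contingency table must be 2x2 with non-negative counts, got {self.O!r}"
            )

    @property
    def row_totals(self) -> np.ndarray:
        return self.O.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.O.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.O.sum())

    @property
    def degenerate(self) -> bool:
        """True when any row or column margin is zero (test undefined)."""
        return bool((self.row_totals == 0).any() or (self.col_totals == 0).any())


@dataclass(slots=True)
class ChiSquareOutcome:
    chi2: float
    yates_used: bool
    degenerate: bool


@dataclass(slots=True)
class AssociationResult:
    """Per-window association test outcome."""

    window: Window
    table: ContingencyTable
    chi2: float
    yates_used: bool
    df: int
    critical_value: float
    significant: bool
    p_value: float
    C: float
    degenerate: bool


def make_table(matrix: TipMatrix, window: Window) -> ContingencyTable:
    """Cross window presence (Y) with the condition label (X)."""
    presence = matrix.column(window)  # raises LookupError for unknown window
    labels = matrix.label_array()
    O = np.zeros((2, 2), dtype=np.int64)
    for y in (0, 1):
        for x in (0, 1):
            O[y, x] = int(((presence == y) & (labels == x)).sum())
    return ContingencyTable(O=O)


def expected_frequencies(table: ContingencyTable) -> np.ndarray:
    """e_ij = n_i. * n_.j / n. Grand total of e equals the grand total of O."""
    if table.n == 0:
        raise DegenerateTableError("cannot compute expected frequencies: n == 0")
    return np.outer(table.row_totals, table.col_totals) / table.n


def chi_square(table: ContingencyTable, yates_mode: YatesMode = "floored") -> ChiSquareOutcome:
    """The chi-square statistic, with Yates' correction when min e_ij < 5.

    A table with a zero row or column margin is reported as degenerate
    (chi2 = 0) rather than raising: the test is undefined there, and
    dropping the window silently would corrupt the window count m.
    """
    if yates_mode not in ("floored", "literal"):
        raise ConfigurationError(f"unknown yates_mode {yates_mode!r}")
    if table.degenerate:
        return ChiSquareOutcome(chi2=0.0, yates_used=False, degenerate=True)
    e = expected_frequencies(table)
    dev = np.abs(table.O - e)
    if e.min() >= YATES_MIN_EXPECTED:
        chi2 = float((dev**2 / e).sum())
        return ChiSquareOutcome(chi2=chi2, yates_used=False, degenerate=False)
    corrected = dev - 0.5
    if yates_mode == "floored":
        corrected = np.maximum(corrected, 0.0)
    chi2 = float((corrected**2 / e).sum())
    return ChiSquareOutcome(chi2=chi2, yates_used=True, degenerate=False)


def decide(chi2: float, alpha: float = 0.05, df: int = 1) -> tuple[float, bool, float]:
    """Rejection criterion: chi2 >= upper-alpha quantile of chi^2_df."""
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    if df < 1:
        raise ConfigurationError(f"df must be >= 1, got {df}")
    critical = float(stats.chi2.ppf(1.0 - alpha, df))
    p_value = float(stats.chi2.sf(chi2, df))
    return critical, chi2 >= critical, p_value


def contingency_coefficient(chi2: float, n: int, mode: CMode = "sqrt") -> float:
    """Association strength in [0, 1): Pearson's C (sqrt) or the unrooted ratio."""
    if n <= 0:
        raise DegenerateTableError(f"contingency coefficient undefined for n={n}")
    if chi2 < 0:
        raise ConfigurationError(f"chi2 must be >= 0, got {chi2}")
    ratio = chi2 / (n + chi2)
    if mode == "sqrt":
        return math.sqrt(ratio)
    if mode == "literal":
        return ratio
    raise ConfigurationError(f"unknown contingency-coefficient mode {mode!r}")


def associate_window(
    matrix: TipMatrix,
    window: Window,
    alpha: float = 0.05,
    yates_mode: YatesMode = "floored",
    c_mode: CMode = "sqrt",
) -> AssociationResult:
    table = make_table(matrix, window)
    outcome = chi_square(table, yates_mode)
    critical, significant, p_value = decide(outcome.chi2, alpha, df=1)
    if outcome.degenerate:
        significant, p_value = False, 1.0
    return AssociationResult(
        window=window,
        table=table,
        chi2=outcome.chi2,
        yates_used=outcome.yates_used,
        df=1,
        critical_value=critical,
        significant=significant,
        p_value=p_value,
        C=contingency_coefficient(outcome.chi2, table.n, c_mode),
        degenerate=outcome.degenerate,
    )


def associate_all(
    matrix: TipMatrix,
    alpha: float = 0.05,
    yates_mode: YatesMode = "floored",
    c_mode: CMode = "sqrt",
    correction: Correction = "none",
) -> list[AssociationResult]:
    """Test every window column of the matrix.

    With ``correction="none"`` (default) significance is the per-test
    criterion chi2 >= chi^2_{alpha,1}. ``bonferroni`` and ``bh``
    (Benjamini-Hochberg) instead compare adjusted p-values against alpha;
    degenerate windows take adjusted p = 1.
    """
    labels = matrix.label_array()
    if matrix.n == 0 or labels.min() == labels.max():
        raise LabelingError("cohort must contain at least one case and one control")
    results = [
        associate_window(matrix, w, alpha=alpha, yates_mode=yates_mode, c_mode=c_mode)
        for w in matrix.windows
    ]
    if correction != "none" and results:
        m = len(results)
        pvals = np.array([r.p_value for r in results])
        if correction == "bonferroni":
            adjusted = np.minimum(pvals * m, 1.0)
        elif correction == "bh":
            order = np.argsort(pvals)
            ranked = pvals[order] * m / np.arange(1, m + 1)
            ranked = np.minimum.accumulate(ranked[::-1])[::-1]
            adjusted = np.empty(m)
            adjusted[order] = np.minimum(ranked, 1.0)
        else:
            raise ConfigurationError(f"unknown correction {correction!r}")
        for r, p_adj in zip(results, adjusted):
            r.significant = (not r.degenerate) and bool(p_adj <= alpha)
    return results


def per_chromosome_counts(results: Sequence[AssociationResult]) -> dict[str, int]:
    """Significant-window counts grouped by chromosome, in natural order."""
    counts: dict[str, int] = {}
    for r in results:
        counts.setdefault(r.window[0], 0)
        if r.significant:
            counts[r.window[0]] += 1
    return {c: counts[c] for c in sorted(counts, key=natural_key)}


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        O = r.table.O
        rows.append(
            {
                "chrom": r.window[0],
                "start": r.window[1],
                "end": r.window[2],
                "O00": O[0, 0],
                "O01": O[0, 1],
                "O10": O[1, 0],
                "O11": O[1, 1],
                "chi2": r.chi2,
                "yates_used": r.yates_used,
                "p_value": r.p_value,
                "significant": r.significant,
                "C": r.C,
                "degenerate": r.degenerate,
            }
        )
    return pd.DataFrame(rows)


def write_results_tsv(results: Sequence[AssociationResult], dest: Union[str, Path, IO[str]]) -> None:
    results_to_frame(results).to_csv(dest, sep="\t", index=False)
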