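"""Prevalence statistics and chi-square association screening.

Reproduces the descriptive / screening stage of the pipeline: per-mille AE
prevalences in the outcome and non-outcome groups, uncorrected Pearson
chi-square tests of association on 2x2 tables with a Bonferroni-style
fixed alpha (default .001 = .05 / 50 candidate AEs), the direction of each
significant association, and a cohort-vs-cohort prevalence comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as _chi2_dist

from .report_io import CaseMatrix

__all__ = [
    "ContingencyTable2x2",
    "ScreeningRecord",
    "CohortComparison",
    "prevalence_per_mille",
    "reconstruct_count",
    "chi_square_2x2",
    "screen_aes",
    "compare_cohorts",
]

DEFAULT_ALPHA = 0.001


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for a 2x2 exposure-by-event table.

    ``a`` = exposed & event, ``b`` = exposed & no event, ``c`` = unexposed &
    event, ``d`` = unexposed & no event.
    """

    a: int
    b: int
    c: int
    d: int
    row_label: str = "exposure"
    col_label: str = "event"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class ScreeningRecord:
    """Association-screening result for one AE term."""

    term: str
    prevalence_overall: float  # per mille
    prevalence_event_group: float
    prevalence_nonevent_group: float
    chi2: float | None
    p_value: float | None
    significant: bool
    direction: str  # "positive", "negative" or "none"


@dataclass(frozen=True)
class CohortComparison:
    """Cohort-vs-cohort prevalence test for one AE term."""

    term: str
    chi2: float | None
    p_value: float | None
    differs: bool
    testable: bool


def prevalence_per_mille(count: int, group_size: int) -> float:
    """Prevalence expressed per 1,000 reports, at full precision."""
    if group_size <= 0:
        raise ValueError("group_size must be positive")
    if not 0 <= count <= group_size:
        raise ValueError("count must lie in [0, group_size]")
    return 1000.0 * count / group_size


def reconstruct_count(per_mille: float | str, group_size: int) -> int:
    """Invert a rounded per-mille value back to the integer count.

    Published tables print prevalences rounded to two decimals; as long as
    0.005 * group_size / 1000 < 0.5 the nearest-integer inverse is exact.
    The sentinel string ``"<0.01"`` denotes a prevalence printed as below
    0.01 per mille, which at the relevant group sizes can only be 0 cases.
    """
    if group_size <= 0:
        raise ValueError("group_size must be positive")
    if isinstance(per_mille, str):
        if per_mille.replace(" ", "") in {"<0.01", "<.01"}:
            return 0
        per_mille = float(per_mille)
    if per_mille < 0:
        raise ValueError("per-mille value must be non-negative")
    return int(round(per_mille * group_size / 1000.0))


def chi_square_2x2(
    table: ContingencyTable2x2, continuity_correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square statistic and two-sided p-value (1 df).

    Uncorrected by default: X^2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)).
    A Yates-corrected variant is available behind the flag.
    """
    r1, r2, c1, c2 = table.margins()
    if min(r1, r2, c1, c2) == 0:
        raise ValueError(f"degenerate margin in 2x2 table {table}")
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    n = a + b + c + d
    diff = abs(a * d - b * c)
    if continuity_correction:
        diff = max(diff - n / 2.0, 0.0)
    stat = n * diff**2 / (r1 * r2 * c1 * c2)
    return stat, float(_chi2_dist.sf(stat, 1))


def screen_aes(
    matrix: CaseMatrix, alpha: float = DEFAULT_ALPHA
) -> list[ScreeningRecord]:
    """Test each AE variable for association with the outcome.

    Returns one record per binary AE variable (all variables except the
    outcome, age and gender) with group prevalences, the uncorrected
    Pearson chi-square p-value, significance at strict ``p < alpha``, and
    the direction of association.  AEs absent from every report are
    untestable: ``p_value`` is None and the direction "none".
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    outcome = matrix.column(matrix.outcome).astype(bool)
    n_event = int(outcome.sum())
    n_nonevent = int((~outcome).sum())
    if n_event == 0 or n_nonevent == 0:
        raise ValueError("both outcome groups must be non-empty for screening")

    records: list[ScreeningRecord] = []
    skip = {matrix.outcome, "age", "gender"}
    for var in matrix.variables:
        if var.name in skip:
            continue
        col = matrix.column(var.name).astype(bool)
        a = int((col & outcome).sum())
        c = int((col & ~outcome).sum())
        prev_event = prevalence_per_mille(a, n_event)
        prev_nonevent = prevalence_per_mille(c, n_nonevent)
        prev_all = prevalence_per_mille(a + c, n_event + n_nonevent)
        if a + c == 0 or (a + c) == matrix.n:
            records.append(
                ScreeningRecord(var.name, prev_all, prev_event, prev_nonevent,
                                None, None, False, "none")
            )
            continue
        stat, p = chi_square_2x2(
            ContingencyTable2x2(a, n_event - a, c, n_nonevent - c,
                                row_label=matrix.outcome, col_label=var.name)
        )
        significant = p < alpha
        if not significant:
            direction = "none"
        elif prev_event > prev_nonevent:
            direction = "positive"
        else:
            direction = "negative"
        records.append(
            ScreeningRecord(var.name, prev_all, prev_event, prev_nonevent,
                            stat, p, significant, direction)
        )
    return records


def compare_cohorts(
    cohort1: Sequence[tuple[str, int, int]],
    cohort2: Sequence[tuple[str, int, int]],
    alpha: float = DEFAULT_ALPHA,
) -> list[CohortComparison]:
    """Per-term cohort-by-presence chi-square test of total prevalence.

    Each cohort is a list of ``(term, count, group_size)``.  Terms present
    in neither cohort are untestable and flagged rather than tested; they
    never count as "no difference".
    """
    lookup2 = {t: (c, n) for t, c, n in cohort2}
    results: list[CohortComparison] = []
    for term, c1, n1 in cohort1:
        if term not in lookup2:
            raise KeyError(f"term {term!r} missing from second cohort")
        c2, n2 = lookup2[term]
        if c1 + c2 == 0:
            results.append(CohortComparison(term, None, None, False, False))
            continue
        stat, p = chi_square_2x2(
            ContingencyTable2x2(c1, n1 - c1, c2, n2 - c2,
                                row_label="cohort", col_label=term)
        )
        results.append(CohortComparison(term, stat, p, p < alpha, True))
    return results


def screening_table(records: list[ScreeningRecord]) -> "pd.DataFrame":
    """Screening results as a DataFrame mirroring the published layout."""
    import pandas as pd

    return pd.DataFrame(
        {
            "term": [r.term for r in records],
            "total_per_mille": [r.prevalence_overall for r in records],
            "event_per_mille": [r.prevalence_event_group for r in records],
            "nonevent_per_mille": [r.prevalence_nonevent_group for r in records],
            "chi2": [r.chi2 for r in records],
            "p_value": [r.p_value for r in records],
            "significant": [r.significant for r in records],
            "direction": [r.direction for r in records],
        }
    )
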