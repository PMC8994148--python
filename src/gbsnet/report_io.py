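"""Reading, cleaning and discretising adverse-event report tables.

Raw pharmacovigilance data (VAERS-style spontaneous reports) arrive as one
row per report: an identifier, the vaccinee's age and gender, and the set of
MedDRA-preferred-term adverse events (AEs) recorded on the report.  This
module turns such tables into the discrete case matrix consumed by
structure learning, screening and validation: a binary outcome column, a
four-level age group, binary gender, and one binary indicator per AE term.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AGE_GROUP_LABELS",
    "AGE_BIN_EDGES",
    "GENDER_LABELS",
    "Report",
    "ReportTable",
    "Variable",
    "CaseMatrix",
    "ReportSchema",
    "load_reports",
    "apply_exclusions",
    "discretize_age",
    "select_top_k_aes",
    "build_case_matrix",
]

#: Age-group labels, in increasing order.  Ages below 0.5 years are excluded
#: before discretisation, so the four half-open bins
#: [0.5, 18), [18, 50), [50, 65), [65, inf) partition every admissible age.
AGE_GROUP_LABELS: tuple[str, ...] = ("0.5-17", "18-49", "50-64", ">=65")
AGE_BIN_EDGES: tuple[float, ...] = (0.5, 18.0, 50.0, 65.0)

GENDER_LABELS: tuple[str, ...] = ("female", "male")

_MALE_TOKENS = {"m", "male", "man", "men"}
_FEMALE_TOKENS = {"f", "female", "woman", "women"}


def normalize_term(term: str) -> str:
    """Canonical AE-term form: trimmed, case-folded, inner whitespace squeezed."""
    return re.sub(r"\s+", " ", term.strip()).casefold()


@dataclass(frozen=True)
class Report:
    """A single adverse-event report."""

    report_id: str
    age: float | None  # years; None when missing
    gender: str  # "male", "female" or "unknown"
    ae_terms: frozenset[str]  # normalised preferred terms
    outcome: bool  # whether the outcome term was reported


@dataclass
class ReportTable:
    """An ordered collection of reports with unique identifiers."""

    records: list[Report]
    outcome_term: str

    def __post_init__(self) -> None:
        ids = Counter(r.report_id for r in self.records)
        dupes = [i for i, c in ids.items() if c > 1]
        if dupes:
            raise ValueError(f"duplicate report_id values: {sorted(dupes)[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass(frozen=True)
class Variable:
    """A discrete variable: its name and ordered state labels."""

    name: str
    states: tuple[str, ...]

    @property
    def cardinality(self) -> int:
        return len(self.states)


@dataclass
class CaseMatrix:
    """Discrete per-report data: rows are reports, columns are variables.

    ``data`` holds state indices (row ``i``, column ``j`` is the index into
    ``variables[j].states``).  The first columns are conventionally the
    outcome, age group and gender, followed by one binary column per AE.
    """

    variables: list[Variable]
    data: np.ndarray
    outcome: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.variables):
            raise ValueError("data shape does not match variable list")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        if self.outcome not in names:
            raise ValueError(f"outcome variable {self.outcome!r} not present")
        for j, v in enumerate(self.variables):
            col = self.data[:, j]
            if col.size and (col.min() < 0 or col.max() >= v.cardinality):
                raise ValueError(f"invalid state index in column {v.name!r}")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def column(self, name: str) -> np.ndarray:
        return self.data[:, self.names.index(name)]

    def variable(self, name: str) -> Variable:
        return self.variables[self.names.index(name)]

    def cardinality(self, name: str) -> int:
        return self.variable(name).cardinality

    def subset_rows(self, idx: np.ndarray) -> "CaseMatrix":
        return CaseMatrix(self.variables, self.data[idx], self.outcome)

    def to_dataframe(self) -> pd.DataFrame:
        """State-label representation, one column per variable."""
        cols = {
            v.name: pd.Categorical.from_codes(
                self.data[:, j].astype(int), categories=list(v.states)
            )
            for j, v in enumerate(self.variables)
        }
        return pd.DataFrame(cols)

    def write(self, path: str | Path, sep: str = ",") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index=False)


@dataclass
class ReportSchema:
    """Column mapping for delimited report files.

    AE terms come either from a single list column (``ae_list_col`` split on
    ``ae_list_sep``) or from one 0/1 indicator column per term
    (``ae_indicator_cols``); exactly one of the two must be given.
    """

    id_col: str
    age_col: str
    gender_col: str
    ae_list_col: str | None = None
    ae_list_sep: str = ";"
    ae_indicator_cols: Sequence[str] | None = None
    outcome_term: str = "guillain-barre syndrome"

    def __post_init__(self) -> None:
        if (self.ae_list_col is None) == (self.ae_indicator_cols is None):
            raise ValueError(
                "exactly one of ae_list_col / ae_indicator_cols must be set"
            )


def _parse_age(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    if not text:
        return None
    try:
        age = float(text)
    except ValueError:
        return None
    return age if np.isfinite(age) else None


def _parse_gender(value) -> str:
    token = str(value).strip().casefold() if value is not None else ""
    if token in _MALE_TOKENS:
        return "male"
    if token in _FEMALE_TOKENS:
        return "female"
    return "unknown"


def load_reports(path: str | Path, schema: ReportSchema, sep: str = ",") -> ReportTable:
    """Read a delimited report file into a :class:`ReportTable`.

    Unparseable or empty age cells become missing values (reports are only
    dropped later, by :func:`apply_exclusions`); unrecognised gender strings
    become ``"unknown"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"report file not found: {path}")
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    needed = [schema.id_col, schema.age_col, schema.gender_col]
    if schema.ae_list_col is not None:
        needed.append(schema.ae_list_col)
    else:
        needed.extend(schema.ae_indicator_cols)
    for col in needed:
        if col not in frame.columns:
            raise KeyError(f"schema column {col!r} not found in {path.name}")

    outcome = normalize_term(schema.outcome_term)
    records: list[Report] = []
    for _, row in frame.iterrows():
        if schema.ae_list_col is not None:
            raw = row[schema.ae_list_col]
            terms = frozenset(
                normalize_term(t)
                for t in str(raw).split(schema.ae_list_sep)
                if t.strip()
            )
        else:
            terms = frozenset(
                normalize_term(c)
                for c in schema.ae_indicator_cols
                if str(row[c]).strip() in {"1", "true", "True", "yes"}
            )
        records.append(
            Report(
                report_id=str(row[schema.id_col]),
                age=_parse_age(row[schema.age_col]),
                gender=_parse_gender(row[schema.gender_col]),
                ae_terms=terms,
                outcome=outcome in terms,
            )
        )
    return ReportTable(records, outcome_term=outcome)


def apply_exclusions(table: ReportTable) -> tuple[ReportTable, dict[str, int]]:
    """Drop reports with missing age, age < 0.5 years, or unknown gender.

    Age rules take precedence in the log: a report failing both an age rule
    and the gender rule is counted once, under the age rule.  Returns the
    retained table and a log with counts per rule plus ``retained``.
    """
    log = {"missing_age": 0, "age_below_half_year": 0, "unknown_gender": 0}
    kept: list[Report] = []
    for rec in table.records:
        if rec.age is None:
            log["missing_age"] += 1
        elif rec.age < 0.5:
            log["age_below_half_year"] += 1
        elif rec.gender not in ("male", "female"):
            log["unknown_gender"] += 1
        else:
            kept.append(rec)
    log["retained"] = len(kept)
    return ReportTable(kept, outcome_term=table.outcome_term), log


def discretize_age(age: float) -> str:
    """Map an age in years (>= 0.5) to its four-level age-group label.

    Bins are half-open: [0.5, 18), [18, 50), [50, 65), [65, inf); e.g. 17.6
    falls in "0.5-17" and 65 in ">=65".
    """
    if age < 0.5:
        raise ValueError(f"age {age} < 0.5: exclusions must run before discretisation")
    idx = int(np.searchsorted(AGE_BIN_EDGES, age, side="right")) - 1
    return AGE_GROUP_LABELS[idx]


def select_top_k_aes(
    table: ReportTable, k: int, exclude: Iterable[str] = ()
) -> list[str]:
    """The ``k`` most prevalent AE terms, excluding the outcome term.

    Prevalence is report-level (number of reports carrying the term).  Ties
    are broken lexicographically so the ranking is reproducible.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    excluded = {normalize_term(t) for t in exclude}
    excluded.add(normalize_term(table.outcome_term))
    counts: Counter[str] = Counter()
    for rec in table.records:
        counts.update(t for t in rec.ae_terms if t not in excluded)
    if len(counts) < k:
        raise ValueError(
            f"only {len(counts)} distinct AE terms available, need {k}"
        )
    ranked = sorted(counts.items(), key=lambda item: (-item[1], item[0]))
    return [term for term, _ in ranked[:k]]


def build_case_matrix(
    table: ReportTable,
    ae_vocabulary: Sequence[str],
    outcome_term: str | None = None,
    outcome_name: str = "GBS",
) -> CaseMatrix:
    """Assemble the discrete case matrix: outcome, age group, gender, AEs.

    Variable order is outcome, age, gender, then the vocabulary terms in the
    order given.  An AE cell is true iff the term occurs in the report's
    term set.  The table must already have passed :func:`apply_exclusions`.
    """
    outcome = normalize_term(outcome_term or table.outcome_term)
    vocab = [normalize_term(t) for t in ae_vocabulary]
    if outcome in vocab:
        raise ValueError(f"outcome term {outcome!r} may not appear in the vocabulary")
    if len(set(vocab)) != len(vocab):
        raise ValueError("duplicate terms in AE vocabulary")

    variables = [
        Variable(outcome_name, ("false", "true")),
        Variable("age", AGE_GROUP_LABELS),
        Variable("gender", GENDER_LABELS),
        *(Variable(t, ("false", "true")) for t in vocab),
    ]
    n = len(table.records)
    data = np.zeros((n, len(variables)), dtype=np.int8)
    age_labels = {lab: i for i, lab in enumerate(AGE_GROUP_LABELS)}
    for i, rec in enumerate(table.records):
        if rec.age is None or rec.age < 0.5 or rec.gender not in GENDER_LABELS:
            raise ValueError("case matrix requires an exclusion-cleaned table")
        if outcome == normalize_term(table.outcome_term):
            data[i, 0] = rec.outcome
        else:
            data[i, 0] = outcome in rec.ae_terms
        data[i, 1] = age_labels[discretize_age(rec.age)]
        data[i, 2] = GENDER_LABELS.index(rec.gender)
    for j, term in enumerate(vocab):
        data[:, 3 + j] = np.fromiter(
            (term in rec.ae_terms for rec in table.records), dtype=np.int8, count=n
        )
    return CaseMatrix(variables, data, outcome_name)
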