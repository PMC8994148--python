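"""Published surveillance summary statistics used as reference inputs.

Aggregate statistics of two influenza-vaccine adverse-event cohorts: US
trivalent-influenza-vaccine (FLU3) reports from VAERS, 1990-2017, and
European influenza-vaccine reports from EudraVigilance, 2003-2016.  The
raw report-level data are not redistributable, but the published
report counts and per-mille AE prevalences are sufficient to reconstruct
every 2x2 table the screening stage needs: per-mille values were printed
rounded to two decimals, which at these group sizes inverts exactly to
integer counts (see :func:`gbsnet.screening.reconstruct_count`).

The per-mille columns for each AE term are ordered (total, GBS group,
non-GBS group); the sentinel string ``"<0.01"`` reproduces the tables'
below-printable entries and denotes zero cases.
"""

from __future__ import annotations

from dataclasses import dataclass

from .screening import reconstruct_count

__all__ = [
    "CohortSummary",
    "US_COHORT",
    "EU_COHORT",
    "TOP50_PREVALENCE",
    "screening_counts",
    "total_counts",
]


@dataclass(frozen=True)
class CohortSummary:
    """Report counts of one surveillance cohort, by outcome group."""

    name: str
    n_total: int
    n_event: int  # GBS reports
    n_nonevent: int
    #: GBS-group report counts per age group (0.5-17, 18-49, 50-64, >=65)
    event_age_counts: tuple[int, int, int, int]
    #: male report counts (GBS group, non-GBS group)
    event_male: int
    nonevent_male: int

    def event_fraction(self) -> float:
        return self.n_event / self.n_total

    def event_male_fraction(self) -> float:
        return self.event_male / self.n_event

    def event_age_fractions(self) -> tuple[float, ...]:
        return tuple(c / self.n_event for c in self.event_age_counts)


US_COHORT = CohortSummary(
    name="US FLU3 (VAERS 1990-2017)",
    n_total=79_165,
    n_event=996,
    n_nonevent=78_169,
    event_age_counts=(57, 276, 326, 337),
    event_male=505,
    nonevent_male=23_327,
)

EU_COHORT = CohortSummary(
    name="European influenza vaccines (EudraVigilance 2003-2016)",
    n_total=12_495,
    n_event=214,
    n_nonevent=12_281,
    event_age_counts=(6, 48, 74, 86),
    event_male=125,
    nonevent_male=4_949,
)

# Per-mille prevalences of the 50 most prevalent US AEs, for the US cohort
# (total, GBS, non-GBS) and the European cohort (total, GBS, non-GBS).
TOP50_PREVALENCE: list[tuple[str, object, object, object, object, object, object]] = [
    ("pyrexia", 138.85, 58.23, 139.88, 140.86, 79.44, 141.93),
    ("injection-site erythema", 126.36, 2.01, 127.94, 15.53, 0, 15.80),
    ("pain", 125.40, 113.45, 125.55, 29.77, 112.15, 28.34),
    ("injection-site pain", 119.16, 7.03, 120.58, 30.97, 4.67, 31.43),
    ("erythema", 89.69, 3.01, 90.79, 23.37, 4.67, 23.70),
    ("pain in extremity", 86.79, 73.29, 86.97, 46.74, 177.57, 44.46),
    ("injection-site swelling", 86.07, 3.01, 87.13, 12.48, 0, 12.70),
    ("headache", 77.52, 61.24, 77.73, 103.16, 88.79, 103.41),
    ("pruritus", 71.33, 2.01, 72.22, 23.53, 18.69, 23.61),
    ("chills", 68.46, 22.09, 69.06, 37.21, 32.71, 37.29),
    ("dizziness", 63.45, 32.13, 63.85, 60.02, 65.42, 59.93),
    ("nausea", 62.70, 25.10, 63.18, 55.14, 23.36, 55.70),
    ("urticaria", 60.75, 2.01, 61.49, 27.85, 0, 28.34),
    ("rash", 59.50, 10.04, 60.13, 26.57, 9.35, 26.87),
    ("injection-site warmth", 55.91, "<0.01", 56.62, 4.08, 0, 4.15),
    ("dyspnea", 50.67, 57.23, 50.58, 47.94, 70.09, 47.55),
    ("myalgia", 49.52, 49.20, 49.52, 66.43, 56.07, 66.61),
    ("vomiting", 45.60, 26.10, 45.85, 42.26, 37.38, 42.34),
    ("asthenia", 44.78, 296.18, 41.58, 39.62, 121.50, 38.19),
    ("fatigue", 37.96, 59.24, 37.69, 72.91, 135.51, 71.82),
    ("paresthesia", 37.57, 332.33, 33.81, 43.06, 345.79, 37.78),
    ("cough", 37.16, 32.13, 37.23, 38.02, 23.36, 38.27),
    ("edema, peripheral", 35.20, 9.04, 35.54, 5.52, 4.67, 5.54),
    ("malaise", 32.22, 27.11, 32.29, 55.62, 56.07, 55.61),
    ("skin, warm", 31.34, 1.00, 31.73, 1.92, 0, 1.95),
    ("hypesthesia", 31.31, 289.16, 28.03, 26.65, 285.05, 22.15),
    ("swelling", 30.76, 3.01, 31.11, 5.28, 0, 5.37),
    ("arthralgia", 28.59, 19.08, 28.71, 39.06, 37.38, 39.08),
    ("injection-site edema", 28.09, 1.00, 28.44, 2.40, 0, 2.44),
    ("injection-site hypersensitivity", 26.38, 2.01, 26.69, 0.24, 0, 0.24),
    ("diarrhea", 24.30, 24.10, 24.31, 27.29, 42.06, 27.03),
    ("hyperhidrosis", 23.08, 7.03, 23.28, 18.65, 9.35, 18.81),
    ("tremor", 21.82, 14.06, 21.91, 9.68, 32.71, 9.28),
    ("injection-site pruritus", 21.26, "<0.01", 21.53, 3.60, 0, 3.66),
    ("injected-limb mobility decreased", 20.78, 2.01, 21.02, 2.96, 0, 3.01),
    ("feeling hot", 19.88, "<0.01", 20.14, 10.40, 9.35, 10.42),
    ("injection-site reaction", 19.39, 1.00, 19.62, 8.48, 0, 8.63),
    ("musculoskeletal pain", 18.91, 12.05, 19.00, 11.20, 46.73, 10.59),
    ("injection-site induration", 18.86, "<0.01", 19.10, 4.16, 0, 4.23),
    ("cellulitis", 18.63, 1.00, 18.86, 2.16, 0, 2.20),
    ("muscular weakness", 17.75, 230.92, 15.03, 25.13, 266.36, 20.93),
    ("vasodilatation", 17.61, 2.01, 17.81, 0.32, 0, 0.33),
    ("neck pain", 17.51, 16.06, 17.53, 7.20, 4.67, 7.25),
    ("mobility decreased", 16.32, 24.10, 16.22, 3.92, 14.02, 3.75),
    ("immediate postinjection reaction", 16.28, 3.01, 16.45, 0, 0, 0),
    ("chest pain", 16.21, 18.07, 16.18, 13.93, 14.02, 13.92),
    ("rash, erythematous", 15.61, 2.01, 15.79, 4.88, 0, 4.97),
    ("injection-site rash", 15.45, 1.00, 15.63, 1.36, 0, 1.38),
    ("syncope", 15.42, 8.03, 15.52, 29.21, 4.67, 29.64),
    ("tenderness", 15.40, 3.01, 15.56, 1.20, 4.67, 1.14),
]


def screening_counts(cohort: str) -> list[tuple[str, int, int]]:
    """Reconstructed (term, GBS-group count, non-GBS-group count) per AE."""
    if cohort == "us":
        summary, gi, ni = US_COHORT, 2, 3
    elif cohort == "eu":
        summary, gi, ni = EU_COHORT, 5, 6
    else:
        raise ValueError("cohort must be 'us' or 'eu'")
    return [
        (
            row[0],
            reconstruct_count(row[gi], summary.n_event),
            reconstruct_count(row[ni], summary.n_nonevent),
        )
        for row in TOP50_PREVALENCE
    ]


def total_counts(cohort: str) -> list[tuple[str, int, int]]:
    """Reconstructed (term, total count, cohort size) per AE."""
    if cohort == "us":
        summary, ti = US_COHORT, 1
    elif cohort == "eu":
        summary, ti = EU_COHORT, 4
    else:
        raise ValueError("cohort must be 'us' or 'eu'")
    return [
        (row[0], reconstruct_count(row[ti], summary.n_total), summary.n_total)
        for row in TOP50_PREVALENCE
    ]
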