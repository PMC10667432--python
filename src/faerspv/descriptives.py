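"""Demographic and clinical summary of the target cohort.

Produces the standard pharmacovigilance descriptive table: sex, age bands,
top indications, seriousness and outcome tallies, reporting year, top
reporter countries, reporter occupation and time-to-onset bins, each with a
count and a percentage of the total cohort.

Percentages use the full cohort size as denominator (not the non-missing
subtotal) and are rounded half-up at two decimals — the convention that
makes a printed numerator/denominator pair reproducible.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from . import tto
from .preprocess import ReportRecord

#: Age bands in years: [low, high) except the open-ended last band.
AGE_BANDS = (("<18", 0, 18), ("18-<45", 18, 45), ("45-<65", 45, 65),
             (">=65", 65, None))

SEX_LABELS = {"F": "Female", "M": "Male"}

OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-Threatening",
    "HO": "Hospitalization - Initial or Prolonged",
    "DS": "Disability",
    "CA": "Congenital Anomaly",
    "RI": "Required Intervention to Prevent Permanent Impairment",
    "OT": "Other serious medical events",
}

OCCUPATION_LABELS = {"MD": "Physician", "PH": "Pharmacist", "CN": "Consumer",
                     "": "Unknown"}


def percentage(count: int, total: int) -> float:
    """Exact half-up percentage at two decimals: 1767 of 2069 -> 85.40."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclasses.dataclass(frozen=True)
class CategoryRow:
    label: str
    count: int
    pct: float


@dataclasses.dataclass(frozen=True)
class CohortSummary:
    total_reports: int
    sex: tuple[CategoryRow, ...]
    age_band: tuple[CategoryRow, ...]
    indications: tuple[CategoryRow, ...]
    seriousness: tuple[CategoryRow, ...]
    outcomes: tuple[CategoryRow, ...]
    year: tuple[CategoryRow, ...]
    countries: tuple[CategoryRow, ...]
    occupation: tuple[CategoryRow, ...]
    tto_bins: tuple[CategoryRow, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = [("Number of reports", "", self.total_reports, "")]
        for section, cat in [("Sex", self.sex), ("Age", self.age_band),
                             ("Indications", self.indications),
                             ("AE Severity", self.seriousness),
                             ("Serious Outcome", self.outcomes),
                             ("Reporting Year", self.year),
                             ("Reported Countries", self.countries),
                             ("Reported Person", self.occupation),
                             ("Time to onset", self.tto_bins)]:
            for r in cat:
                rows.append((section, r.label, r.count, f"{r.pct:.2f}"))
        return pd.DataFrame(rows, columns=["section", "category", "n", "pct"])


def _rows(counts: Counter, total: int, order: Sequence[str]) -> tuple[CategoryRow, ...]:
    return tuple(CategoryRow(label, counts.get(label, 0),
                             percentage(counts.get(label, 0), total))
                 for label in order)


def _top_k(counts: Counter, total: int, k: int) -> tuple[CategoryRow, ...]:
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return tuple(CategoryRow(label, n, percentage(n, total))
                 for label, n in ordered)


def _age_band(age: float | None) -> str:
    if age is None:
        return "Unknown"
    for label, lo, hi in AGE_BANDS:
        if age >= lo and (hi is None or age < hi):
            return label
    return "Unknown"


def summarize_cohort(cohort: Sequence[ReportRecord], k: int = 5) -> CohortSummary:
    """Summarize the target cohort; top-k lists break count ties
    alphabetically for determinism. Raises on an empty cohort."""
    total = len(cohort)
    if total == 0:
        raise ValueError("cannot summarize an empty cohort")

    sex = Counter(SEX_LABELS.get(r.sex, "Unknown") for r in cohort)
    age = Counter(_age_band(r.age_years) for r in cohort)
    serious = Counter("Serious" if r.serious else "Non-serious"
                      for r in cohort)
    year = Counter(r.year or "Unknown" for r in cohort)
    country = Counter(r.reporter_country or "Unknown" for r in cohort)
    occupation = Counter(
        OCCUPATION_LABELS.get(r.occupation, r.occupation or "Unknown")
        for r in cohort)

    indications: Counter = Counter()
    for r in cohort:
        indications.update(set(r.indications))

    outcomes: Counter = Counter()
    for r in cohort:
        for code in r.outcome_codes:
            outcomes[OUTCOME_LABELS.get(code, "unknown")] += 1

    obs = tto.onset_observations(cohort)
    summary = tto.summarize_tto(obs)
    tto_rows = tuple(
        CategoryRow(label, n, percentage(n, total))
        for label, n in zip(tto.BIN_LABELS, summary.bin_counts))

    age_order = [b[0] for b in AGE_BANDS] + ["Unknown"]
    return CohortSummary(
        total_reports=total,
        sex=_rows(sex, total, ["Female", "Male", "Unknown"]),
        age_band=_rows(age, total, age_order),
        indications=_top_k(indications, total, k),
        seriousness=_rows(serious, total, ["Serious", "Non-serious"]),
        outcomes=tuple(CategoryRow(label, outcomes.get(label, 0),
                                   percentage(outcomes.get(label, 0), total))
                       for label in OUTCOME_LABELS.values()
                       if outcomes.get(label, 0) or label != "Congenital Anomaly"),
        year=_rows(year, total, sorted(year)),
        countries=_top_k(country, total, k),
        occupation=tuple(CategoryRow(label, n, percentage(n, total))
                         for label, n in sorted(occupation.items(),
                                                key=lambda kv: (-kv[1], kv[0]))),
        tto_bins=tto_rows,
    )
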