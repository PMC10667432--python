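"""Time-to-onset (TTO) of target-drug adverse events.

TTO is the calendar-day interval between therapy start (earliest
full-precision START_DT of the primary-suspect target drug rows) and event
onset (EVENT_DT). Reports with either date missing, either date at partial
(year or month) precision, or a start later than the event are excluded,
each with an explicit reason, so that every target report falls in exactly
one bucket: included or one of four exclusion reasons.

Summaries report mean, median and quartiles (linear interpolation between
order statistics by default — printed fractional quartiles such as 0.50
rule out nearest-rank) and counts in the day-range bins 0-30, 31-90,
91-180, 181-360 and >360.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Sequence

import numpy as np
import pandas as pd

from . import _dates
from .preprocess import ReportRecord

MISSING_START = "missing_start"
MISSING_EVENT = "missing_event"
PARTIAL_DATE = "partial_date"
NEGATIVE_INTERVAL = "negative_interval"
INCLUDED = "included"

EXCLUSION_REASONS = (MISSING_START, MISSING_EVENT, PARTIAL_DATE,
                     NEGATIVE_INTERVAL)

#: (low, high) day bins; high None = open-ended. Bounds are inclusive whole
#: days, so day 30 falls in 0-30 and day 31 in 31-90.
BINS: tuple[tuple[int, int | None], ...] = (
    (0, 30), (31, 90), (91, 180), (181, 360), (361, None))

BIN_LABELS = ("0-30d", "31-90d", "91-180d", "181-360d", ">360d")


@dataclasses.dataclass(frozen=True)
class OnsetObservation:
    """One report's resolved onset interval or its exclusion reason."""

    primaryid: str
    pt: str | None
    start_dt: str
    event_dt: str
    onset_days: int | None
    exclusion_reason: str | None

    @property
    def included(self) -> bool:
        return self.exclusion_reason is None


@dataclasses.dataclass(frozen=True)
class TtoSummary:
    n_with_onset: int
    mean: float
    median: float
    q1: float
    q3: float
    bin_counts: tuple[int, ...]

    def as_dict(self) -> dict:
        d = {"n": self.n_with_onset, "mean": self.mean,
             "median": self.median, "q1": self.q1, "q3": self.q3}
        d.update(zip(BIN_LABELS, self.bin_counts))
        return d


def compute_onset(report: ReportRecord, pt: str | None = None) -> OnsetObservation:
    """Resolve one target report to onset days or an exclusion reason.

    Reason precedence when several apply: missing_start (no START_DT at
    all for the matched drug rows) > missing_event > partial_date (either
    date below day precision) > negative_interval (start after event).
    """
    start_raw = report.target_start_raw
    event = report.event_dt
    start = report.target_start_dt

    def obs(days, reason):
        return OnsetObservation(report.primaryid, pt, start, event, days,
                                reason)

    if not start_raw:
        return obs(None, MISSING_START)
    if not event:
        return obs(None, MISSING_EVENT)
    if not start or not _dates.is_full(event):
        # start dates exist but none at day precision, or partial event
        return obs(None, PARTIAL_DATE)
    days = _dates.days_between(start, event)
    if days < 0:
        return obs(None, NEGATIVE_INTERVAL)
    return obs(days, None)


def onset_observations(cohort: Sequence[ReportRecord]) -> list[OnsetObservation]:
    """One observation per target report (Table-2-style overall TTO)."""
    return [compute_onset(r) for r in cohort]


def pt_onset_observations(cohort: Sequence[ReportRecord]) -> list[OnsetObservation]:
    """One observation per (report, PT) pair (per-event TTO)."""
    out = []
    for r in cohort:
        for name in r.event_names:
            out.append(compute_onset(r, pt=name))
    return out


def exclusion_partition(obs: Sequence[OnsetObservation]) -> Counter:
    """Counts per bucket; values sum to len(obs) by construction."""
    return Counter(o.exclusion_reason or INCLUDED for o in obs)


def _bin_index(days: int) -> int:
    for i, (lo, hi) in enumerate(BINS):
        if days >= lo and (hi is None or days <= hi):
            return i
    raise ValueError(f"negative onset {days}")


def summarize_tto(obs: Sequence[OnsetObservation],
                  quantile_method: str = "linear") -> TtoSummary:
    """Summarize included observations; n=0 yields an all-NaN summary."""
    days = np.array([o.onset_days for o in obs if o.included], dtype=float)
    if days.size == 0:
        return TtoSummary(0, np.nan, np.nan, np.nan, np.nan,
                          (0,) * len(BINS))
    q1, med, q3 = np.percentile(days, [25, 50, 75], method=quantile_method)
    counts = [0] * len(BINS)
    for v in days:
        counts[_bin_index(int(v))] += 1
    return TtoSummary(int(days.size), float(days.mean()), float(med),
                      float(q1), float(q3), tuple(counts))


def summarize_by_pt(cohort: Sequence[ReportRecord], min_n: int = 1,
                    quantile_method: str = "linear") -> pd.DataFrame:
    """Per-PT TTO table (event, n with recorded onset, median, Q1, Q3),
    sorted by n descending then event name. PTs are grouped
    case-insensitively; the alphabetically first display form is shown."""
    from .ingest import normalize_term

    by_pt: dict[str, list[OnsetObservation]] = {}
    display: dict[str, str] = {}
    for o in pt_onset_observations(cohort):
        key = normalize_term(o.pt)
        by_pt.setdefault(key, []).append(o)
        if key not in display or o.pt < display[key]:
            display[key] = o.pt
    rows = []
    for key, observations in by_pt.items():
        s = summarize_tto(observations, quantile_method)
        if s.n_with_onset >= min_n and s.n_with_onset > 0:
            rows.append({"event": display[key], "n": s.n_with_onset,
                         "median": s.median, "q1": s.q1, "q3": s.q3,
                         "mean": s.mean})
    df = pd.DataFrame(rows, columns=["event", "n", "median", "q1", "q3",
                                     "mean"])
    return df.sort_values(["n", "event"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
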