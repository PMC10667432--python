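"""Report cleaning and cohort construction.

Three stages between raw quarterly tables and analysis-ready records:

1. :func:`drop_deleted` removes reports whose CASEID appears on the FDA's
   deleted-report list.
2. :func:`deduplicate` collapses report versions: FAERS re-publishes a case
   under new PRIMARYIDs as follow-up information arrives, so within each
   CASEID only the version with the latest FDA receipt date (FDA_DT) is
   kept, ties broken by the numerically highest PRIMARYID.
3. :func:`build_cohort` flattens every surviving report into a
   :class:`ReportRecord` and flags reports where the target drug appears as
   primary suspect (PS) — the exposure definition used throughout.

Drug matching is case-insensitive substring matching against both DRUGNAME
(verbatim, often a brand name) and PROD_AI (active ingredient), so that
suffixed biologic names ("-hziy") and formatting noise still match.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import pandas as pd

from . import _dates
from .ingest import RawTables, normalize_term

#: AGE_COD -> multiplier converting AGE to years. Codes outside this table
#: (including DEC, which FAERS defines as decades but is rare and ambiguous
#: in practice) yield a missing age.
AGE_FACTORS = {"YR": 1.0, "MON": 1 / 12, "WK": 1 / 52.14, "DY": 1 / 365.25}

#: Outcome codes counted as serious: death, life-threatening,
#: hospitalization, disability, congenital anomaly, required intervention,
#: other serious medical event.
SERIOUS_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")


@dataclasses.dataclass(frozen=True)
class ReportRecord:
    """One deduplicated safety report, flattened for analysis."""

    primaryid: str
    caseid: str
    fda_dt: str
    event_dt: str
    age_years: float | None
    sex: str
    occupation: str
    reporter_country: str
    year: str
    outcome_codes: frozenset[str]
    serious: bool
    indications: tuple[str, ...]
    events: frozenset[str]          # normalized PT keys
    event_names: tuple[str, ...]    # display forms, aligned with sorted keys
    is_target_ps: bool
    target_start_raw: tuple[str, ...]  # all START_DT strings of matched PS rows
    target_start_dt: str               # earliest full-precision one, or ""


def age_in_years(age: str, age_cod: str) -> float | None:
    """Harmonize AGE + AGE_COD to years; unparseable or unknown-unit -> None."""
    try:
        value = float(age)
    except (TypeError, ValueError):
        return None
    factor = AGE_FACTORS.get(age_cod.strip().upper())
    if factor is None:
        return None
    return value * factor


def drop_deleted(raw: RawTables) -> RawTables:
    """Remove reports whose CASEID is on the deleted list.

    Deleted CASEIDs absent from the data are a no-op, counted under
    ``deleted_not_present``.
    """
    counters = Counter(raw.counters)
    if not raw.deleted:
        counters["deleted_removed"] = 0
        return raw.replace(counters=counters)
    demo = raw.demo
    mask = ~demo["CASEID"].isin(raw.deleted)
    counters["deleted_removed"] = int((~mask).sum())
    present = set(demo.loc[~mask, "CASEID"])
    counters["deleted_not_present"] = len(raw.deleted - present)
    return _filter_to_demo(raw, demo[mask], counters)


def deduplicate(raw: RawTables) -> RawTables:
    """Keep one report version per CASEID.

    Within each CASEID the surviving row has the latest FDA_DT; ties on
    FDA_DT are broken by the numerically highest PRIMARYID. Rows with a
    missing CASEID cannot be linked to other versions and are kept as
    singletons (counted under ``missing_caseid``). Child-table rows of
    discarded versions are dropped with them. Idempotent.
    """
    counters = Counter(raw.counters)
    demo = raw.demo.copy()
    fda_key = demo["FDA_DT"].map(_dates.sort_key)
    pid_key = pd.to_numeric(demo["PRIMARYID"], errors="coerce").fillna(-1.0)
    order = demo.assign(_fda=fda_key, _pid=pid_key)

    has_case = order["CASEID"].str.len() > 0
    counters["missing_caseid"] = int((~has_case).sum())

    keyed = order[has_case]
    best_idx = (keyed.sort_values(["_fda", "_pid"], kind="mergesort")
                     .groupby("CASEID", sort=False).tail(1).index)
    keep = demo.loc[sorted(set(best_idx) | set(order.index[~has_case]))]
    counters["duplicates_removed"] = len(demo) - len(keep)
    return _filter_to_demo(raw, keep, counters)


def _filter_to_demo(raw: RawTables, demo: pd.DataFrame,
                    counters: Counter) -> RawTables:
    keep_ids = set(demo["PRIMARYID"])
    new = {"demo": demo.reset_index(drop=True)}
    for name in ("drug", "reac", "ther", "outc", "indi"):
        df = raw.tables()[name]
        new[name] = df[df["PRIMARYID"].isin(keep_ids)].reset_index(drop=True)
    return raw.replace(counters=counters, **new)


def _group_rows(df: pd.DataFrame) -> dict[str, list[tuple]]:
    """PRIMARYID -> list of row tuples (excluding the PRIMARYID column)."""
    out: dict[str, list[tuple]] = {}
    cols = [c for c in df.columns if c != "PRIMARYID"]
    for row in df[["PRIMARYID", *cols]].itertuples(index=False):
        out.setdefault(row[0], []).append(tuple(row[1:]))
    return out


def build_cohort(raw: RawTables, patterns: list[str]) -> list[ReportRecord]:
    """Flatten every report to a :class:`ReportRecord`, flagging target
    exposure.

    A report is target-exposed iff at least one drug row matches a pattern
    (case-insensitive substring on DRUGNAME or PROD_AI) *and* that row's
    ROLE_COD is PS. ``target_start_dt`` is the earliest full-precision
    START_DT among matching PS drug rows, joined THER.DSG_DRUG_SEQ =
    DRUG.DRUG_SEQ.
    """
    pats = [p.casefold() for p in patterns]
    drugs = _group_rows(raw.drug)     # (DRUG_SEQ, ROLE_COD, DRUGNAME, PROD_AI)
    reacs = _group_rows(raw.reac)     # (PT,)
    thers = _group_rows(raw.ther)     # (DSG_DRUG_SEQ, START_DT)
    outcs = _group_rows(raw.outc)     # (OUTC_COD,)
    indis = _group_rows(raw.indi)     # (INDI_DRUG_SEQ, INDI_PT)

    records: list[ReportRecord] = []
    for row in raw.demo.itertuples(index=False):
        pid = row.PRIMARYID
        matched_ps_seqs = []
        for seq, role, name, prod_ai in drugs.get(pid, []):
            text = f"{name}\n{prod_ai}".casefold()
            if role.strip().upper() == "PS" and any(p in text for p in pats):
                matched_ps_seqs.append(seq)
        is_target = bool(matched_ps_seqs)

        start_raw: tuple[str, ...] = ()
        start_dt = ""
        if is_target:
            seqs = set(matched_ps_seqs)
            start_raw = tuple(st for seq, st in thers.get(pid, [])
                              if seq in seqs and st)
            full = [st for st in start_raw if _dates.is_full(st)]
            start_dt = min(full) if full else ""

        pt_display: dict[str, str] = {}
        for (pt,) in reacs.get(pid, []):
            key = normalize_term(pt)
            if key:
                disp = " ".join(pt.split())
                if key not in pt_display or disp < pt_display[key]:
                    pt_display[key] = disp
        keys = tuple(sorted(pt_display))

        codes = frozenset(c.strip().upper() for (c,) in outcs.get(pid, [])
                          if c.strip())
        records.append(ReportRecord(
            primaryid=pid,
            caseid=row.CASEID,
            fda_dt=row.FDA_DT,
            event_dt=row.EVENT_DT,
            age_years=age_in_years(row.AGE, row.AGE_COD),
            sex=row.SEX.strip().upper(),
            occupation=row.OCCP_COD.strip().upper(),
            reporter_country=row.REPORTER_COUNTRY.strip(),
            year=row.FDA_DT[:4] if row.FDA_DT else "",
            outcome_codes=codes,
            serious=bool(codes),
            indications=tuple(sorted({" ".join(ipt.split())
                                      for _, ipt in indis.get(pid, []) if ipt.strip()})),
            events=frozenset(keys),
            event_names=tuple(pt_display[k] for k in keys),
            is_target_ps=is_target,
            target_start_raw=start_raw,
            target_start_dt=start_dt,
        ))
    return records


def classify_seriousness(record: ReportRecord) -> tuple[str, Counter]:
    """Label a report Serious/Non-serious and tally its outcome codes.

    Serious iff the outcome-code set is non-empty (DE, LT, HO, DS, CA, RI,
    OT). Unknown codes are tallied under ``unknown`` and still count as
    serious: any outcome row marks a serious report.
    """
    tally: Counter = Counter()
    for code in record.outcome_codes:
        tally[code if code in SERIOUS_CODES else "unknown"] += 1
    label = "Serious" if record.outcome_codes else "Non-serious"
    return label, tally


def target_cohort(records: list[ReportRecord]) -> list[ReportRecord]:
    """The primary-suspect target cohort."""
    return [r for r in records if r.is_target_ps]
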