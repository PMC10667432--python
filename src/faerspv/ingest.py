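"""Readers for FAERS-style quarterly ASCII files and the PT->SOC mapping.

The FDA distributes FAERS quarters as ``$``-delimited ASCII tables with one
header row: DEMO (one row per report version), DRUG, REAC, THER, OUTC and
INDI (child tables keyed by PRIMARYID), plus a list of deleted CASEIDs.
This module parses those files into :class:`RawTables` — pandas DataFrames
with string-typed cells — validating date fields and counting, never hiding,
malformed rows.

MedDRA itself is licensed, so the PT->SOC mapping is a user-supplied
two-column file loaded by :func:`load_meddra_map`.
"""

from __future__ import annotations

import dataclasses
import re
from collections import Counter
from pathlib import Path

import pandas as pd

from . import _dates

#: Column layout of each table. Cells are kept as strings; numeric join keys
#: (DRUG_SEQ etc.) are compared as strings on both sides.
TABLE_COLUMNS: dict[str, list[str]] = {
    "demo": [
        "PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "AGE", "AGE_COD",
        "SEX", "OCCP_COD", "REPORTER_COUNTRY", "OCCR_COUNTRY",
    ],
    "drug": ["PRIMARYID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME", "PROD_AI"],
    "reac": ["PRIMARYID", "PT"],
    "ther": ["PRIMARYID", "DSG_DRUG_SEQ", "START_DT"],
    "outc": ["PRIMARYID", "OUTC_COD"],
    "indi": ["PRIMARYID", "INDI_DRUG_SEQ", "INDI_PT"],
}

DATE_COLUMNS: dict[str, list[str]] = {
    "demo": ["FDA_DT", "EVENT_DT"],
    "ther": ["START_DT"],
}

UNMAPPED = "UNMAPPED"

_WS = re.compile(r"\s+")


@dataclasses.dataclass
class Dialect:
    """File dialect for the quarterly ASCII layout.

    Defaults follow the FDA convention: ``$`` delimiter, first row header,
    UTF-8 with a latin-1 fallback for stray bytes in free-text fields.
    """

    delimiter: str = "$"
    encoding: str = "utf-8"
    fallback_encoding: str = "latin-1"


@dataclasses.dataclass
class RawTables:
    """One quarter (or a concatenation of quarters) of raw report tables."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    indi: pd.DataFrame
    deleted: frozenset[str] = frozenset()
    counters: Counter = dataclasses.field(default_factory=Counter)

    @property
    def n_reports(self) -> int:
        return len(self.demo)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_COLUMNS}

    def replace(self, **kwargs) -> "RawTables":
        return dataclasses.replace(self, **kwargs)


def empty_tables() -> RawTables:
    return RawTables(**{
        name: pd.DataFrame(columns=cols).astype(str)
        for name, cols in TABLE_COLUMNS.items()
    })


def _decode(data: bytes, dialect: Dialect) -> str:
    try:
        return data.decode(dialect.encoding)
    except UnicodeDecodeError:
        return data.decode(dialect.fallback_encoding)


def _read_table(path: Path, name: str, dialect: Dialect,
                counters: Counter) -> pd.DataFrame:
    """Parse one ``$``-delimited table, skipping rows with the wrong field
    count (counted under ``skipped_rows:<name>``) and blanking malformed
    dates (counted under ``malformed_dates:<name>``)."""
    columns = TABLE_COLUMNS[name]
    date_cols = {columns.index(c) for c in DATE_COLUMNS.get(name, [])}
    text = _decode(path.read_bytes(), dialect)
    lines = text.splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file (missing header row)")
    header = [h.strip().upper() for h in lines[0].split(dialect.delimiter)]
    # Map our canonical columns onto whatever order the file uses.
    try:
        positions = [header.index(c) for c in columns]
    except ValueError as exc:
        raise ValueError(f"{path}: header is missing a required column "
                         f"({exc})") from None
    rows: list[list[str]] = []
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.split(dialect.delimiter)
        if len(fields) != len(header):
            counters[f"skipped_rows:{name}"] += 1
            continue
        row = [fields[i].strip() for i in positions]
        for j in date_cols:
            validated = _dates.validate_date(row[j])
            if validated is None:
                counters[f"malformed_dates:{name}"] += 1
                validated = ""
            row[j] = validated
        rows.append(row)
    counters[f"rows:{name}"] = len(rows)
    return pd.DataFrame(rows, columns=columns, dtype=str)


def _find_file(dir_path: Path, stem: str) -> Path | None:
    hits = sorted(p for p in dir_path.iterdir()
                  if p.is_file() and p.name.upper().startswith(stem.upper()))
    return hits[0] if hits else None


def read_deleted(path: Path, dialect: Dialect | None = None) -> frozenset[str]:
    """Read the deleted-report list: one CASEID per line (delimited rows are
    tolerated; the first field is taken)."""
    dialect = dialect or Dialect()
    out = set()
    text = _decode(Path(path).read_bytes(), dialect)
    for line in text.splitlines():
        caseid = line.split(dialect.delimiter)[0].strip()
        if caseid and caseid.upper() != "CASEID":
            out.add(caseid)
    return frozenset(out)


def read_quarter(dir_path: str | Path, dialect: Dialect | None = None,
                 deleted_path: str | Path | None = None) -> RawTables:
    """Read one quarter directory into :class:`RawTables`.

    Each of the six mandatory tables is located by filename prefix
    (``DEMO*``, ``DRUG*``, ...). A ``DELETED*`` file is optional, or an
    explicit ``deleted_path`` may point anywhere. Child-table rows whose
    PRIMARYID has no DEMO row are dropped and counted as orphans.
    """
    dir_path = Path(dir_path)
    dialect = dialect or Dialect()
    counters: Counter = Counter()
    frames: dict[str, pd.DataFrame] = {}
    for name in TABLE_COLUMNS:
        path = _find_file(dir_path, name)
        if path is None:
            raise FileNotFoundError(
                f"mandatory table file {name.upper()}* not found in {dir_path}")
        frames[name] = _read_table(path, name, dialect, counters)

    known = set(frames["demo"]["PRIMARYID"])
    for name in ("drug", "reac", "ther", "outc", "indi"):
        mask = frames[name]["PRIMARYID"].isin(known)
        n_orphans = int((~mask).sum())
        if n_orphans:
            counters[f"orphans:{name}"] = n_orphans
            frames[name] = frames[name][mask].reset_index(drop=True)

    deleted: frozenset[str] = frozenset()
    if deleted_path is not None:
        deleted = read_deleted(Path(deleted_path), dialect)
    else:
        path = _find_file(dir_path, "deleted")
        if path is not None:
            deleted = read_deleted(path, dialect)

    return RawTables(deleted=deleted, counters=counters, **frames)


def concat_tables(parts: list[RawTables]) -> RawTables:
    """Concatenate several quarters into one table set."""
    if not parts:
        return empty_tables()
    counters: Counter = Counter()
    deleted: set[str] = set()
    frames = {}
    for name in TABLE_COLUMNS:
        frames[name] = pd.concat([p.tables()[name] for p in parts],
                                 ignore_index=True)
    for p in parts:
        counters.update(p.counters)
        deleted |= p.deleted
    return RawTables(deleted=frozenset(deleted), counters=counters, **frames)


def write_quarter(raw: RawTables, dir_path: str | Path,
                  dialect: Dialect | None = None) -> None:
    """Write tables back in the same dialect (used by the synthetic generator
    and for round-trip testing)."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    dialect = dialect or Dialect()
    for name, cols in TABLE_COLUMNS.items():
        df = raw.tables()[name]
        lines = [dialect.delimiter.join(cols)]
        for row in df.itertuples(index=False):
            lines.append(dialect.delimiter.join(str(v) for v in row))
        (dir_path / f"{name.upper()}.txt").write_text(
            "\n".join(lines) + "\n", encoding=dialect.encoding)
    (dir_path / "DELETED.txt").write_text(
        "\n".join(sorted(raw.deleted)) + ("\n" if raw.deleted else ""),
        encoding=dialect.encoding)


# ---------------------------------------------------------------------------
# MedDRA PT -> SOC mapping
# ---------------------------------------------------------------------------

def normalize_term(term: str) -> str:
    """Trim, collapse internal whitespace and case-fold a MedDRA term.

    FAERS PT capitalization is inconsistent across quarters, so all PT
    lookups and groupings go through this normalization.
    """
    return _WS.sub(" ", term.strip()).casefold()


class MeddraMap:
    """Primary PT -> SOC mapping with case-insensitive lookup.

    Each PT maps to exactly one SOC (the "primary SOC" convention); a PT
    absent from the map resolves to the ``UNMAPPED`` pseudo-SOC so that
    unmapped terms surface in outputs instead of being dropped.
    """

    def __init__(self, pt_to_soc: dict[str, str],
                 soc_codes: dict[str, str] | None = None):
        self._map = {normalize_term(pt): soc.strip()
                     for pt, soc in pt_to_soc.items()}
        self.soc_codes = dict(soc_codes or {})

    def soc_of(self, pt: str) -> str:
        return self._map.get(normalize_term(pt), UNMAPPED)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, pt: str) -> bool:
        return normalize_term(pt) in self._map

    @property
    def socs(self) -> set[str]:
        return set(self._map.values())


def load_meddra_map(path: str | Path, delimiter: str | None = None) -> MeddraMap:
    """Load a two-column PT,SOC file (comma or tab delimited; sniffed from
    the first line when not given). Duplicate PT rows agreeing on the SOC are
    tolerated; conflicting rows raise with the full conflict list."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty mapping file")
    if delimiter is None:
        delimiter = "\t" if "\t" in lines[0] else ","
    mapping: dict[str, str] = {}
    display: dict[str, str] = {}
    conflicts: list[str] = []
    start = 1 if normalize_term(lines[0].split(delimiter)[0]) in ("pt", "preferred term") else 0
    for ln in lines[start:]:
        parts = ln.split(delimiter)
        if len(parts) < 2:
            raise ValueError(f"{path}: expected 2 columns, got {ln!r}")
        pt, soc = parts[0], delimiter.join(parts[1:])
        key = normalize_term(pt)
        soc = soc.strip()
        if key in mapping and mapping[key] != soc:
            conflicts.append(f"{display[key]!r}: {mapping[key]!r} vs {soc!r}")
        else:
            mapping[key] = soc
            display[key] = pt.strip()
    if conflicts:
        raise ValueError(f"{path}: conflicting PT->SOC rows: "
                         + "; ".join(conflicts))
    return MeddraMap({display[k]: v for k, v in mapping.items()})
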