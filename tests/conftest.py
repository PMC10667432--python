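"""Shared fixtures: a small handcrafted FAERS-style quarter with known
duplicates, deletions, partial dates and malformed rows, plus record
builders for direct construction of analysis inputs."""

from __future__ import annotations

import pytest

from faerspv.preprocess import ReportRecord

D = "$"

DEMO_HEADER = ("PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "AGE", "AGE_COD",
               "SEX", "OCCP_COD", "REPORTER_COUNTRY", "OCCR_COUNTRY")

# 11 demo rows covering: versioned case C1 (later FDA_DT wins), tied case C2
# (higher PRIMARYID wins), partial dates (C3 start+event, C4 year-only
# FDA_DT), multi-episode therapy (C5), deleted case C6, negative onset (C7),
# non-PS target drug (C8), malformed EVENT_DT (C9).
DEMO_ROWS = [
    ("101", "C1", "20220101", "20220115", "55", "YR", "F", "MD", "US", "US"),
    ("102", "C1", "20220301", "20220115", "55", "YR", "F", "MD", "US", "US"),
    ("100", "C2", "20220210", "", "660", "MON", "M", "PH", "FR", "FR"),
    ("200", "C2", "20220210", "", "660", "MON", "M", "PH", "FR", "FR"),
    ("301", "C3", "20220405", "202203", "", "", "F", "CN", "US", "US"),
    ("401", "C4", "2022", "20220310", "40", "YR", "F", "MD", "CA", "CA"),
    ("501", "C5", "20220601", "20220520", "70", "YR", "M", "MD", "DE", "DE"),
    ("601", "C6", "20220615", "", "", "", "", "", "IT", "IT"),
    ("701", "C7", "20220620", "20220103", "33", "YR", "F", "PH", "US", "US"),
    ("801", "C8", "20220701", "20220710", "29200", "DY", "F", "MD", "US", "US"),
    ("901", "C9", "20220801", "20221332", "19", "YR", "M", "MD", "US", "US"),
]

DRUG_ROWS = [
    ("101", "1", "PS", "TRODELVY", "SACITUZUMAB GOVITECAN-HZIY"),
    ("102", "1", "PS", "TRODELVY", "SACITUZUMAB GOVITECAN-HZIY"),
    ("100", "1", "C", "TRODELVY", ""),
    ("100", "2", "PS", "OTHERDRUG", "OTHER INGREDIENT"),
    ("200", "1", "C", "TRODELVY", ""),
    ("200", "2", "PS", "OTHERDRUG", "OTHER INGREDIENT"),
    ("301", "1", "PS", "UNKNOWN", "sacituzumab govitecan-hziy"),
    ("401", "1", "PS", "OTHERDRUG", ""),
    ("501", "1", "PS", "TRODELVY", ""),
    ("501", "2", "PS", "TRODELVY", ""),
    ("601", "1", "PS", "TRODELVY", ""),
    ("701", "1", "PS", "TRODELVY", ""),
    ("801", "1", "SS", "TRODELVY", ""),
    ("901", "1", "PS", "OTHERDRUG", ""),
]

REAC_ROWS = [
    ("101", "Neutropenia"),
    ("102", "Neutropenia"),
    ("102", "Diarrhoea"),
    ("100", "Neutropenia"),
    ("200", "Neutropenia"),
    ("301", "Colitis"),
    ("401", "Nausea"),
    ("501", "NEUTROPENIA "),   # exercises PT normalization
    ("601", "Sepsis"),
    ("701", "Diarrhoea"),
    ("801", "Nausea"),
    ("901", "Vomiting"),
]

THER_ROWS = [
    ("102", "1", "20220101"),
    ("301", "1", "202201"),      # month precision only
    ("501", "1", "20220110"),
    ("501", "2", "20220103"),
    ("701", "1", "20220201"),
]

OUTC_ROWS = [
    ("101", "HO"),
    ("102", "HO"),
    ("102", "OT"),
    ("200", "DE"),
    ("401", "OT"),
    ("501", "HO"),
    ("601", "DE"),
    ("701", "OT"),
    ("801", "LT"),
]

INDI_ROWS = [
    ("102", "1", "Triple negative breast cancer"),
    ("301", "1", "Triple negative breast cancer"),
    ("501", "1", "Breast cancer metastatic"),
    ("701", "1", "Triple negative breast cancer"),
]

MEDDRA_ROWS = [
    ("Neutropenia", "Blood and lymphatic system disorders"),
    ("Diarrhoea", "Gastrointestinal disorders"),
    ("Colitis", "Gastrointestinal disorders"),
    ("Nausea", "Gastrointestinal disorders"),
    ("Vomiting", "Gastrointestinal disorders"),
    ("Sepsis", "Infections and infestations"),
]

TARGET_PATTERNS = ["sacituzumab govitecan", "trodelvy"]


def write_table(path, header, rows, bad_lines=()):
    lines = [D.join(header)]
    lines += [D.join(r) for r in rows]
    lines += list(bad_lines)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_fixture_quarter(dir_path, demo=DEMO_ROWS, drug=DRUG_ROWS,
                          reac=REAC_ROWS, ther=THER_ROWS, outc=OUTC_ROWS,
                          indi=INDI_ROWS, deleted=("C6",), reac_bad=()):
    dir_path.mkdir(parents=True, exist_ok=True)
    write_table(dir_path / "DEMO.txt", DEMO_HEADER, demo)
    write_table(dir_path / "DRUG.txt",
                ("PRIMARYID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME", "PROD_AI"),
                drug)
    write_table(dir_path / "REAC.txt", ("PRIMARYID", "PT"), reac,
                bad_lines=reac_bad)
    write_table(dir_path / "THER.txt",
                ("PRIMARYID", "DSG_DRUG_SEQ", "START_DT"), ther)
    write_table(dir_path / "OUTC.txt", ("PRIMARYID", "OUTC_COD"), outc)
    write_table(dir_path / "INDI.txt",
                ("PRIMARYID", "INDI_DRUG_SEQ", "INDI_PT"), indi)
    (dir_path / "DELETED.txt").write_text("\n".join(deleted) + "\n")
    return dir_path


@pytest.fixture
def quarter_dir(tmp_path):
    return write_fixture_quarter(tmp_path / "q1")


@pytest.fixture
def meddra_file(tmp_path):
    path = tmp_path / "meddra_map.csv"
    path.write_text("\n".join(f"{pt},{soc}" for pt, soc in MEDDRA_ROWS) + "\n")
    return path


def make_record(primaryid="1", caseid=None, events=(), is_target=False,
                start_raw=(), start_dt="", event_dt="", outcome_codes=(),
                sex="F", age=None, **kw):
    """Minimal ReportRecord for tests that construct cohorts directly."""
    from faerspv.ingest import normalize_term
    keys = sorted(normalize_term(e) for e in events)
    by_key = {normalize_term(e): " ".join(e.split()) for e in events}
    defaults = dict(
        primaryid=primaryid, caseid=caseid or primaryid,
        fda_dt="20220601", event_dt=event_dt, age_years=age, sex=sex,
        occupation="MD", reporter_country="US", year="2022",
        outcome_codes=frozenset(outcome_codes),
        serious=bool(outcome_codes),
        indications=(), events=frozenset(keys),
        event_names=tuple(by_key[k] for k in keys),
        is_target_ps=is_target, target_start_raw=tuple(start_raw),
        target_start_dt=start_dt)
    defaults.update(kw)
    return ReportRecord(**defaults)
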