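"""Deleted-report removal, version deduplication, cohort construction and
seriousness classification."""

import pandas.testing as pdt
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faerspv import preprocess
from faerspv.ingest import read_quarter
from faerspv.preprocess import (age_in_years, build_cohort,
                                classify_seriousness, deduplicate,
                                drop_deleted, target_cohort)
from faerspv.descriptives import percentage

from conftest import TARGET_PATTERNS, write_fixture_quarter


@pytest.fixture
def raw(quarter_dir):
    return read_quarter(quarter_dir)


class TestDropDeleted:
    def test_removes_deleted_caseids(self, raw):
        out = drop_deleted(raw)
        assert "C6" not in set(out.demo["CASEID"])
        assert out.counters["deleted_removed"] == 1
        # child rows of the removed report go with it
        assert "601" not in set(out.reac["PRIMARYID"])

    def test_empty_deleted_set_is_identity(self, raw):
        out = drop_deleted(raw.replace(deleted=frozenset()))
        pdt.assert_frame_equal(out.demo, raw.demo)
        assert out.counters["deleted_removed"] == 0

    def test_absent_deleted_caseid_is_noop_and_counted(self, raw):
        out = drop_deleted(raw.replace(deleted=frozenset({"NOPE"})))
        assert len(out.demo) == len(raw.demo)
        assert out.counters["deleted_not_present"] == 1


def brute_force_dedup(demo_rows):
    """Independent oracle: per CASEID keep latest FDA_DT, ties by highest
    numeric PRIMARYID."""
    best = {}
    for pid, caseid, fda in demo_rows:
        key = (int(fda.ljust(8, "0")) if fda else -1, int(pid))
        if caseid not in best or key > best[caseid][0]:
            best[caseid] = (key, pid)
    return {pid for _, pid in best.values()}


class TestDeduplicate:
    def test_latest_fda_dt_version_survives(self, raw):
        out = deduplicate(raw)
        c1 = out.demo[out.demo["CASEID"] == "C1"]
        assert list(c1["PRIMARYID"]) == ["102"]

    def test_fda_dt_tie_broken_by_highest_primaryid(self, raw):
        out = deduplicate(raw)
        c2 = out.demo[out.demo["CASEID"] == "C2"]
        assert list(c2["PRIMARYID"]) == ["200"]

    def test_matches_brute_force_oracle(self, raw):
        out = deduplicate(raw)
        expected = brute_force_dedup(
            raw.demo[["PRIMARYID", "CASEID", "FDA_DT"]].itertuples(index=False))
        assert set(out.demo["PRIMARYID"]) == expected

    def test_idempotent(self, raw):
        once = deduplicate(raw)
        twice = deduplicate(once)
        pdt.assert_frame_equal(once.demo, twice.demo)
        for name in ("drug", "reac", "ther", "outc", "indi"):
            pdt.assert_frame_equal(once.tables()[name], twice.tables()[name])

    def test_duplicate_free_data_unchanged(self, tmp_path):
        rows = [("1", "A", "20220101", "", "", "", "F", "MD", "US", "US"),
                ("2", "B", "20220102", "", "", "", "M", "MD", "US", "US")]
        qdir = write_fixture_quarter(tmp_path / "q", demo=rows, drug=[],
                                     reac=[], ther=[], outc=[], indi=[],
                                     deleted=())
        raw = read_quarter(qdir)
        out = deduplicate(raw)
        pdt.assert_frame_equal(out.demo, raw.demo)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.tuples(st.integers(1, 30),        # caseid
                              st.integers(1, 999),       # primaryid
                              st.sampled_from(["20220101", "20220105",
                                               "20220301", "2022", ""])),
                    min_size=1, max_size=40,
                    unique_by=lambda t: t[1]))
    def test_property_matches_oracle_on_random_versions(self, tmp_path_factory,
                                                        rows):
        demo = [(str(pid), f"C{cid}", fda, "", "", "", "F", "MD", "US", "US")
                for cid, pid, fda in rows]
        qdir = write_fixture_quarter(
            tmp_path_factory.mktemp("dedup") / "q", demo=demo, drug=[],
            reac=[], ther=[], outc=[], indi=[], deleted=())
        raw = read_quarter(qdir)
        out = deduplicate(raw)
        expected = brute_force_dedup(
            (str(pid), f"C{cid}", fda) for cid, pid, fda in rows)
        assert set(out.demo["PRIMARYID"]) == expected
        assert out.demo["CASEID"].is_unique


@pytest.fixture
def records(raw):
    return build_cohort(deduplicate(drop_deleted(raw)), TARGET_PATTERNS)


class TestBuildCohort:
    def test_target_flags(self, records):
        flags = {r.primaryid: r.is_target_ps for r in records}
        assert flags["102"]   # DRUGNAME TRODELVY, role PS
        assert flags["301"]   # PROD_AI substring match incl. -hziy suffix
        assert not flags["200"]  # target drug present but role C only
        assert not flags["801"]  # role SS
        assert not flags["401"]
        assert len(target_cohort(records)) == 4

    def test_earliest_full_precision_start_wins(self, records):
        r = {x.primaryid: x for x in records}["501"]
        assert set(r.target_start_raw) == {"20220110", "20220103"}
        assert r.target_start_dt == "20220103"

    def test_partial_start_dates_not_promoted(self, records):
        r = {x.primaryid: x for x in records}["301"]
        assert r.target_start_raw == ("202201",)
        assert r.target_start_dt == ""

    def test_events_normalized_per_report(self, records):
        r = {x.primaryid: x for x in records}["501"]
        assert r.events == {"neutropenia"}

    def test_cohort_not_larger_than_dedup_and_all_targets_match(self, records):
        assert len(target_cohort(records)) <= len(records)
        for r in target_cohort(records):
            assert r.is_target_ps

    def test_age_harmonized_to_years(self, records):
        by_id = {r.primaryid: r for r in records}
        assert by_id["102"].age_years == pytest.approx(55)
        assert by_id["200"].age_years == pytest.approx(55, abs=0.1)   # 660 MON
        assert by_id["801"].age_years == pytest.approx(79.9, abs=0.1)  # DY
        assert by_id["301"].age_years is None


class TestSeriousness:
    def test_multi_code_report_serious_with_full_tally(self, records):
        r = {x.primaryid: x for x in records}["102"]
        label, tally = classify_seriousness(r)
        assert label == "Serious"
        assert tally == {"HO": 1, "OT": 1}

    def test_no_outcome_rows_non_serious(self, records):
        r = {x.primaryid: x for x in records}["301"]
        label, tally = classify_seriousness(r)
        assert label == "Non-serious" and not tally

    def test_unknown_code_still_serious(self, records):
        r = {x.primaryid: x for x in records}["102"]
        odd = preprocess.ReportRecord(**{**r.__dict__,
                                         "outcome_codes": frozenset({"ZZ"})})
        label, tally = classify_seriousness(odd)
        assert label == "Serious" and tally == {"unknown": 1}

    def test_serious_share_on_fixture(self, records):
        # 6 of the 8 surviving reports carry an outcome code (C3 and C9
        # have no OUTC rows)
        serious = sum(r.serious for r in records)
        assert len(records) == 8
        assert percentage(serious, len(records)) == 75.00


@pytest.mark.parametrize("age,cod,expected", [
    ("56", "YR", 56.0),
    ("6", "MON", 0.5),
    ("52.14", "WK", 1.0),
    ("365.25", "DY", 1.0),
    ("5", "DEC", None),    # decade code deliberately unsupported
    ("", "YR", None),
    ("abc", "YR", None),
])
def test_age_in_years(age, cod, expected):
    result = age_in_years(age, cod)
    if expected is None:
        assert result is None
    else:
        assert result == pytest.approx(expected)
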