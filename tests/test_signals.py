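"""Disproportionality algorithms against independent oracles, the consensus
criteria, and screening behaviour on synthetic cohorts."""

import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats
import statsmodels.stats.contingency_tables as smct
from hypothesis import given, settings
from hypothesis import strategies as st

from faerspv.ingest import MeddraMap
from faerspv.signals import (PT_LEVEL, SOC_LEVEL, BcpnnPriors,
                             ContingencyTable, Thresholds, bcpnn_ic,
                             build_contingency, compute_metrics,
                             consensus_signals, ebgm, evaluate_criteria,
                             metrics_frame, prr, ror, screen)

from conftest import make_record

tables = st.builds(ContingencyTable,
                   a=st.integers(1, 500), b=st.integers(1, 500),
                   c=st.integers(1, 500), d=st.integers(1, 500))


class TestRor:
    def test_symmetric_table_is_one(self):
        assert ror(ContingencyTable(50, 50, 50, 50)).ror == 1.0

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(tables)
    def test_matches_statsmodels_oddsratio_and_ci(self, t):
        oracle = smct.Table2x2(np.array([[t.a, t.b], [t.c, t.d]]))
        got = ror(t)
        assert got.ror == pytest.approx(oracle.oddsratio, rel=1e-12)
        lo, hi = oracle.oddsratio_confint(0.05)
        # statsmodels uses the normal quantile 1.95996..., the printed
        # formula uses 1.96 exactly; agree to ~1e-4 relative
        assert got.ci_low == pytest.approx(lo, rel=1e-3)
        assert got.ci_high == pytest.approx(hi, rel=1e-3)
        assert got.ci_low <= got.ror <= got.ci_high

    def test_zero_cell_undefined_no_continuity_correction(self):
        got = ror(ContingencyTable(3, 0, 5, 7))
        assert math.isnan(got.ror) and math.isnan(got.ci_low)


class TestPrr:
    def test_independence_table(self):
        got = prr(ContingencyTable(9, 21, 21, 49))   # a = (a+b)(a+c)/n
        assert got.prr == pytest.approx(1.0)
        assert got.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        got = prr(ContingencyTable(10, 20, 30, 40))
        assert got.prr == pytest.approx(0.7778, abs=5e-5)
        assert got.chi2 == pytest.approx(0.7937, abs=5e-5)

    def test_strong_signal_example(self):
        got = prr(ContingencyTable(30, 10, 10, 50))
        assert got.prr == pytest.approx(4.5)
        assert got.chi2 == pytest.approx(34.03, abs=5e-3)

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(tables)
    def test_chi2_matches_uncorrected_pearson(self, t):
        chi2, _, _, _ = scipy.stats.chi2_contingency(
            np.array([[t.a, t.b], [t.c, t.d]]), correction=False)
        assert prr(t).chi2 == pytest.approx(chi2, rel=1e-10)

    def test_zero_denominator_undefined(self):
        got = prr(ContingencyTable(3, 2, 0, 5))
        assert math.isnan(got.prr)


def ic_moments_fraction_oracle(t, p=BcpnnPriors()):
    """Exact-rational re-evaluation of the shrinkage moments."""
    n, a = Fraction(t.n), Fraction(t.a)
    ab, ac = Fraction(t.a + t.b), Fraction(t.a + t.c)
    al, be = Fraction(p.alpha), Fraction(p.beta)
    al1, be1, g11 = Fraction(p.alpha1), Fraction(p.beta1), Fraction(p.gamma11)
    gamma = g11 * (n + al) * (n + be) / ((ab + al1) * (ac + be1))
    e_arg = (a + g11) * (n + al) * (n + be) / (
        (n + gamma) * (ab + al1) * (ac + be1))
    v = ((n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
         + (n - ab + al - al1) / ((ab + al1) * (1 + n + al))
         + (n - ac + be - be1) / ((ac + be1) * (1 + n + be)))
    return math.log2(e_arg), float(v) / math.log(2) ** 2


class TestBcpnn:
    def test_independence_ic_zero(self):
        assert bcpnn_ic(ContingencyTable(9, 21, 21, 49)).ic == pytest.approx(0)

    def test_worked_example(self):
        got = bcpnn_ic(ContingencyTable(10, 20, 30, 40))
        assert got.ic == pytest.approx(math.log2(1000 / 1200), abs=1e-12)
        e, v = ic_moments_fraction_oracle(ContingencyTable(10, 20, 30, 40))
        assert got.ic_e == pytest.approx(e, rel=1e-12)
        assert got.ic_v == pytest.approx(v, rel=1e-12)
        assert got.ic025 == pytest.approx(e - 2 * math.sqrt(v), rel=1e-12)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(tables)
    def test_moments_match_exact_rational_oracle(self, t):
        got = bcpnn_ic(t)
        e, v = ic_moments_fraction_oracle(t)
        assert got.ic_e == pytest.approx(e, rel=1e-10)
        assert got.ic_v == pytest.approx(v, rel=1e-10)

    def test_shrinkage_vanishes_in_large_n_limit(self):
        # fixed cell ratios 1:2:3:4 scaled up: E(IC) -> IC and V(IC) -> 0
        gaps, vs = [], []
        for scale in (10, 100, 1000, 10000):
            t = ContingencyTable(1 * scale, 2 * scale, 3 * scale, 4 * scale)
            got = bcpnn_ic(t)
            gaps.append(abs(got.ic_e - got.ic))
            vs.append(got.ic_v)
        assert gaps == sorted(gaps, reverse=True)
        assert vs == sorted(vs, reverse=True)
        # V(IC) decays like 1/a: ~2.7e-4 at a = 1e4
        assert gaps[-1] < 1e-4 and vs[-1] < 1e-3

    def test_zero_a_point_ic_undefined_but_shrunken_moments_defined(self):
        got = bcpnn_ic(ContingencyTable(0, 10, 10, 80))
        assert math.isnan(got.ic)
        assert math.isfinite(got.ic_e) and math.isfinite(got.ic025)


class TestEbgm:
    def test_independence_is_one(self):
        assert ebgm(ContingencyTable(9, 21, 21, 49)).ebgm == pytest.approx(1)

    def test_worked_example(self):
        got = ebgm(ContingencyTable(10, 20, 30, 40))
        assert got.ebgm == pytest.approx(Fraction(10 * 100, 30 * 40),
                                         rel=1e-12)
        assert got.ebgm05 < got.ebgm < got.ebgm95

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(tables)
    def test_ic_equals_log2_ebgm_identity(self, t):
        assert bcpnn_ic(t).ic == pytest.approx(math.log2(ebgm(t).ebgm),
                                               rel=1e-12)

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(tables)
    def test_null_crossing_equivalence(self, t):
        """ad > bc iff ROR > 1 iff PRR > 1 iff EBGM > 1 iff IC > 0."""
        above = t.a * t.d > t.b * t.c
        if t.a * t.d == t.b * t.c:
            return
        assert (ror(t).ror > 1) == above
        assert (prr(t).prr > 1) == above
        assert (ebgm(t).ebgm > 1) == above
        assert (bcpnn_ic(t).ic > 0) == above

    def test_monotone_in_a(self):
        vals = [(ror(t).ror, prr(t).prr, ebgm(t).ebgm, bcpnn_ic(t).ic)
                for a in (5, 10, 20, 40)
                for t in [ContingencyTable(a, 50, 60, 400)]]
        for col in zip(*vals):
            assert list(col) == sorted(col)
            assert len(set(col)) == len(col)


class TestCriteria:
    def test_printed_consensus_soc_row(self):
        # Blood/lymphatic SOC-style estimates: every flag positive
        m = compute_metrics("x", ContingencyTable(549, 1520, 40000, 460000))
        m_eval = evaluate_criteria(m)
        assert m_eval.ror_pos and m_eval.prr_pos and m_eval.bcpnn_pos
        assert m_eval.mgps_pos and m_eval.min_count_ok and m_eval.consensus

    def test_protective_ror_fails_consensus(self):
        # ROR below 1 (nervous-system-style row): ror_pos false sinks it
        m = compute_metrics("x", ContingencyTable(261, 1808, 90000, 410000))
        assert m.ror < 1 and not m.ror_pos and not m.consensus

    def test_min_count_rule_beats_huge_ror(self):
        m = compute_metrics("x", ContingencyTable(2, 10, 3, 40000))
        assert m.ror > 100
        assert not m.min_count_ok and not m.consensus

    def test_undefined_metrics_fail_their_flags(self):
        m = compute_metrics("x", ContingencyTable(3, 0, 5, 100))
        assert not m.ror_pos and not m.mgps_pos and not m.consensus

    def test_thresholds_configurable(self):
        m = compute_metrics("x", ContingencyTable(2, 10, 3, 40000),
                            thresholds=Thresholds(min_a=1))
        assert m.min_count_ok


@pytest.fixture
def six_reports():
    return [
        make_record("t1", events=["E", "F"], is_target=True),
        make_record("t2", events=["E"], is_target=True),
        make_record("t3", events=["G"], is_target=True),
        make_record("o1", events=["E"]),
        make_record("o2", events=["E", "G"]),
        make_record("o3", events=["F"]),
    ]


class TestContingencyAndScreen:
    def test_counts_on_six_report_fixture(self, six_reports):
        t = build_contingency(six_reports, "E")
        assert (t.a, t.b, t.c, t.d) == (2, 1, 2, 1)

    def test_report_with_two_pts_in_one_soc_counts_once(self):
        m = MeddraMap({"P1": "S", "P2": "S"})
        records = [make_record("t1", events=["P1", "P2"], is_target=True),
                   make_record("o1", events=["P1"])]
        t = build_contingency(records, "S", level=SOC_LEVEL, meddra=m)
        assert (t.a, t.c) == (1, 1)

    def test_no_nontarget_reports_degenerate_margin(self):
        records = [make_record("t1", events=["E"], is_target=True),
                   make_record("t2", events=["E"], is_target=True),
                   make_record("t3", events=["X"], is_target=True)]
        t = build_contingency(records, "E")
        assert (t.c, t.d) == (0, 0)
        m = compute_metrics("E", t)
        assert not m.consensus  # undefined stats flagged not-positive

    def test_screen_orders_by_count_then_name(self, six_reports):
        out = screen(six_reports)
        assert [m.event for m in out] == ["E", "F", "G"]
        assert [m.a for m in out] == [2, 1, 1]

    def test_excluded_soc_retained_in_raw_dropped_from_consensus(self):
        m = MeddraMap({"Device breakage": "Product issues",
                       "Neutropenia": "Blood"})
        records = (
            [make_record(f"t{i}", events=["Device breakage"], is_target=True)
             for i in range(30)]
            + [make_record(f"u{i}", events=["Neutropenia"], is_target=True)
               for i in range(30)]
            + [make_record(f"o{i}", events=["Other"]) for i in range(900)]
            + [make_record("o_x", events=["Device breakage"]),
               make_record("o_y", events=["Neutropenia"])])
        out = screen(records, meddra=m, soc_exclusions=["Product issues"])
        by_event = {x.event: x for x in out}
        assert by_event["Device breakage"].excluded
        assert by_event["Device breakage"].consensus  # raw flag still computed
        kept = consensus_signals(out)
        assert [x.event for x in kept] == ["Neutropenia"]

    def test_metrics_frame_stable_columns(self, six_reports):
        df = metrics_frame(screen(six_reports))
        assert list(df.columns[:5]) == ["event", "level", "soc", "a", "b"]
        assert len(df) == 3
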