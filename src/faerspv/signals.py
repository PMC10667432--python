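"""Disproportionality screening of drug-event pairs in spontaneous reports.

Spontaneous-report databases have no exposure denominator, so association is
screened through the 2x2 report-level contingency table for one drug and one
event (a MedDRA PT, or an SOC after mapping):

====================  ===========  ============
                      target event  other events
target drug           a             b
all other drugs       c             d
====================  ===========  ============

The counting unit is the deduplicated report: a report contributes at most
one count per cell for a given event, and a report with several PTs inside
one SOC still counts once at SOC level.

Four standard algorithms are computed on each table:

* **ROR** — reporting odds ratio ad/(bc) with a log-normal Wald 95% CI.
* **PRR** — proportional reporting ratio (a/(a+b))/(c/(c+d)) with the
  uncorrected Pearson chi-squared statistic.
* **BCPNN** — the information component IC = log2(a*n/((a+b)(a+c))) with
  Beta-prior shrinkage giving E(IC) and V(IC) in closed form; IC025 =
  E(IC) - 2*sqrt(V(IC)) is the lower uncertainty bound.
* **EBGM** — the empirical-Bayes geometric-mean style observed/expected
  ratio a*n/((a+b)(a+c)) with a log-normal 95% CI (EBGM05 lower bound).
  Note this is the closed-form relative reporting ratio, not the
  DuMouchel gamma-Poisson EM shrinker; the point estimate satisfies
  IC = log2(EBGM) identically.

A drug-event pair is a *consensus signal* when it has at least ``min_a``
reports (default 3) and simultaneously satisfies all four algorithms'
criteria: ROR CI lower bound > 1; PRR >= 2 with chi2 >= 4; IC025 > 0;
EBGM05 > 2. Zero cells receive no continuity correction: estimates that are
undefined on the raw table are returned as NaN and simply fail their
criterion.
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from .ingest import MeddraMap, normalize_term
from .preprocess import ReportRecord

NAN = float("nan")

PT_LEVEL = "PT"
SOC_LEVEL = "SOC"

_Z95 = 1.96


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """Report-level 2x2 counts for one (drug, event) pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.n <= 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclasses.dataclass(frozen=True)
class BcpnnPriors:
    """Beta/Dirichlet prior constants of the BCPNN closed forms.

    The defaults (gamma11 = 1, alpha = beta = 2, alpha1 = beta1 = 1) are the
    standard published choice for the two-way information component.
    """

    alpha: float = 2.0
    beta: float = 2.0
    alpha1: float = 1.0
    beta1: float = 1.0
    gamma11: float = 1.0

    def __post_init__(self):
        if min(self.alpha, self.beta, self.alpha1, self.beta1,
               self.gamma11) <= 0:
            raise ValueError("BCPNN priors must be strictly positive")


@dataclasses.dataclass(frozen=True)
class Thresholds:
    """Consensus criteria; defaults are the conventional screening values."""

    ror_ci_low: float = 1.0    # strict >
    prr: float = 2.0           # >=
    chi2: float = 4.0          # >=
    ic025: float = 0.0         # strict >
    ebgm05: float = 2.0        # strict >
    min_a: int = 3             # >=


class RorResult(NamedTuple):
    ror: float
    ci_low: float
    ci_high: float


class PrrResult(NamedTuple):
    prr: float
    chi2: float


class IcResult(NamedTuple):
    ic: float
    ic_e: float
    ic_v: float
    ic025: float


class EbgmResult(NamedTuple):
    ebgm: float
    ebgm05: float
    ebgm95: float


def _wald_halfwidth(t: ContingencyTable) -> float:
    return _Z95 * math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)


def ror(t: ContingencyTable) -> RorResult:
    """Reporting odds ratio ad/(bc) with log-normal Wald 95% CI.

    Any zero cell makes the estimate or its CI undefined; NaNs are returned
    and later fail the criterion (no continuity correction is applied).
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        return RorResult(NAN, NAN, NAN)
    est = (t.a * t.d) / (t.b * t.c)
    half = _wald_halfwidth(t)
    return RorResult(est, math.exp(math.log(est) - half),
                     math.exp(math.log(est) + half))


def prr(t: ContingencyTable) -> PrrResult:
    """Proportional reporting ratio with the uncorrected Pearson chi2.

    PRR = (a/(a+b)) / (c/(c+d));
    chi2 = (ad-bc)^2 * n / ((a+b)(c+d)(a+c)(b+d)), no Yates correction.
    """
    ab, cd, ac, bd = t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d
    if ab == 0 or cd == 0 or t.c == 0:
        est = NAN
    else:
        est = (t.a / ab) / (t.c / cd)
    if min(ab, cd, ac, bd) == 0:
        chi2 = NAN
    else:
        chi2 = (t.a * t.d - t.b * t.c) ** 2 * t.n / (ab * cd * ac * bd)
    return PrrResult(est, chi2)


def bcpnn_ic(t: ContingencyTable,
             priors: BcpnnPriors | None = None) -> IcResult:
    """Information component with closed-form Beta-shrinkage moments.

    With n = a+b+c+d and gamma = gamma11*(n+alpha)(n+beta) /
    ((a+b+alpha1)(a+c+beta1)):

        E(IC) = log2[ (a+gamma11)(n+alpha)(n+beta)
                      / ((n+gamma)(a+b+alpha1)(a+c+beta1)) ]
        V(IC) = (1/ln2)^2 * [ (n-a+gamma-gamma11) / ((a+gamma11)(1+n+gamma))
                            + (n-(a+b)+alpha-alpha1) / ((a+b+alpha1)(1+n+alpha))
                            + (n-(a+c)+beta-beta1) / ((a+c+beta1)(1+n+beta)) ]
        IC025 = E(IC) - 2*sqrt(V(IC))

    The point IC = log2(a*n/((a+b)(a+c))) is undefined (NaN) when a = 0,
    but the shrunken E(IC) and IC025 remain defined.
    """
    p = priors or BcpnnPriors()
    n, a = t.n, t.a
    ab, ac = t.a + t.b, t.a + t.c
    if a > 0 and ab > 0 and ac > 0:
        ic = math.log2(a * n / (ab * ac))
    else:
        ic = NAN
    gamma = p.gamma11 * (n + p.alpha) * (n + p.beta) / (
        (ab + p.alpha1) * (ac + p.beta1))
    ic_e = math.log2(
        (a + p.gamma11) * (n + p.alpha) * (n + p.beta)
        / ((n + gamma) * (ab + p.alpha1) * (ac + p.beta1)))
    ln2sq = math.log(2) ** 2
    ic_v = (1 / ln2sq) * (
        (n - a + gamma - p.gamma11) / ((a + p.gamma11) * (1 + n + gamma))
        + (n - ab + p.alpha - p.alpha1) / ((ab + p.alpha1) * (1 + n + p.alpha))
        + (n - ac + p.beta - p.beta1) / ((ac + p.beta1) * (1 + n + p.beta)))
    return IcResult(ic, ic_e, ic_v, ic_e - 2 * math.sqrt(ic_v))


def ebgm(t: ContingencyTable) -> EbgmResult:
    """Closed-form EBGM = a*n/((a+b)(a+c)) with log-normal 95% bounds."""
    ab, ac = t.a + t.b, t.a + t.c
    if t.a == 0 or ab == 0 or ac == 0:
        return EbgmResult(NAN, NAN, NAN)
    est = t.a * t.n / (ab * ac)
    if min(t.a, t.b, t.c, t.d) == 0:
        return EbgmResult(est, NAN, NAN)
    half = _wald_halfwidth(t)
    return EbgmResult(est, math.exp(math.log(est) - half),
                      math.exp(math.log(est) + half))


@dataclasses.dataclass(frozen=True)
class SignalMetrics:
    """All four algorithms' estimates and criterion flags for one event."""

    event: str
    level: str
    table: ContingencyTable
    ror: float
    ror_ci_low: float
    ror_ci_high: float
    prr: float
    chi2: float
    ic: float
    ic_e: float
    ic_v: float
    ic025: float
    ebgm: float
    ebgm05: float
    ebgm95: float
    ror_pos: bool
    prr_pos: bool
    bcpnn_pos: bool
    mgps_pos: bool
    min_count_ok: bool
    consensus: bool
    excluded: bool = False
    soc: str = ""

    @property
    def a(self) -> int:
        return self.table.a


def _gt(x: float, threshold: float) -> bool:
    return not math.isnan(x) and x > threshold


def _ge(x: float, threshold: float) -> bool:
    return not math.isnan(x) and x >= threshold


def compute_metrics(event: str, t: ContingencyTable, level: str = PT_LEVEL,
                    priors: BcpnnPriors | None = None,
                    thresholds: Thresholds | None = None,
                    excluded: bool = False, soc: str = "") -> SignalMetrics:
    """Run all four algorithms on one table and evaluate the criteria."""
    th = thresholds or Thresholds()
    r = ror(t)
    p = prr(t)
    i = bcpnn_ic(t, priors)
    e = ebgm(t)
    flags = dict(
        ror_pos=_gt(r.ci_low, th.ror_ci_low),
        prr_pos=_ge(p.prr, th.prr) and _ge(p.chi2, th.chi2),
        bcpnn_pos=_gt(i.ic025, th.ic025),
        mgps_pos=_gt(e.ebgm05, th.ebgm05),
        min_count_ok=t.a >= th.min_a,
    )
    return SignalMetrics(
        event=event, level=level, table=t,
        ror=r.ror, ror_ci_low=r.ci_low, ror_ci_high=r.ci_high,
        prr=p.prr, chi2=p.chi2,
        ic=i.ic, ic_e=i.ic_e, ic_v=i.ic_v, ic025=i.ic025,
        ebgm=e.ebgm, ebgm05=e.ebgm05, ebgm95=e.ebgm95,
        consensus=all(flags.values()), excluded=excluded, soc=soc,
        **flags)


def evaluate_criteria(m: SignalMetrics,
                      thresholds: Thresholds | None = None) -> SignalMetrics:
    """Re-evaluate the five flags and consensus on existing estimates."""
    th = thresholds or Thresholds()
    flags = dict(
        ror_pos=_gt(m.ror_ci_low, th.ror_ci_low),
        prr_pos=_ge(m.prr, th.prr) and _ge(m.chi2, th.chi2),
        bcpnn_pos=_gt(m.ic025, th.ic025),
        mgps_pos=_gt(m.ebgm05, th.ebgm05),
        min_count_ok=m.a >= th.min_a,
    )
    return dataclasses.replace(m, consensus=all(flags.values()), **flags)


def _event_sets(records: Sequence[ReportRecord], level: str,
                meddra: MeddraMap | None) -> tuple[list[frozenset], dict[str, str]]:
    """Per-report event-key sets plus key -> display-name map."""
    display: dict[str, str] = {}
    sets = []
    for r in records:
        if level == PT_LEVEL:
            keys = set(r.events)
            for k, name in zip(sorted(r.events), r.event_names):
                if k not in display or name < display[k]:
                    display[k] = name
        elif level == SOC_LEVEL:
            if meddra is None:
                raise ValueError("SOC-level screening requires a MedDRA map")
            keys = set()
            for name in r.event_names:
                soc = meddra.soc_of(name)
                key = normalize_term(soc)
                keys.add(key)
                if key not in display or soc < display[key]:
                    display[key] = soc
        else:
            raise ValueError(f"unknown level {level!r}")
        sets.append(frozenset(keys))
    return sets, display


def build_contingency(records: Sequence[ReportRecord], event: str,
                      level: str = PT_LEVEL,
                      meddra: MeddraMap | None = None) -> ContingencyTable:
    """Count the 2x2 table for one event label over the full report set."""
    key = normalize_term(event)
    sets, _ = _event_sets(records, level, meddra)
    a = b = c = d = 0
    for r, keys in zip(records, sets):
        has = key in keys
        if r.is_target_ps:
            a, b = a + has, b + (not has)
        else:
            c, d = c + has, d + (not has)
    return ContingencyTable(a, b, c, d)


def screen(records: Sequence[ReportRecord], level: str = PT_LEVEL,
           meddra: MeddraMap | None = None,
           soc_exclusions: Iterable[str] = (),
           priors: BcpnnPriors | None = None,
           thresholds: Thresholds | None = None) -> list[SignalMetrics]:
    """Screen every event observed in target reports at the given level.

    Returns one :class:`SignalMetrics` per distinct event with a >= 1,
    sorted by a descending then event name. Events belonging to an excluded
    SOC are retained with ``excluded=True`` (use :func:`consensus_signals`
    for the filtered consensus report).
    """
    sets, display = _event_sets(records, level, meddra)
    excl = {normalize_term(s) for s in soc_exclusions}

    n_target = sum(r.is_target_ps for r in records)
    n_other = len(records) - n_target
    a_counts: Counter = Counter()
    c_counts: Counter = Counter()
    for r, keys in zip(records, sets):
        (a_counts if r.is_target_ps else c_counts).update(keys)

    out = []
    for key, a in a_counts.items():
        c = c_counts.get(key, 0)
        t = ContingencyTable(a, n_target - a, c, n_other - c)
        if level == SOC_LEVEL:
            soc_key, soc_name = key, display[key]
        else:
            soc_name = meddra.soc_of(display[key]) if meddra else ""
            soc_key = normalize_term(soc_name)
        out.append(compute_metrics(
            display[key], t, level=level, priors=priors,
            thresholds=thresholds,
            excluded=soc_key in excl, soc=soc_name))
    out.sort(key=lambda m: (-m.a, m.event))
    return out


def consensus_signals(metrics: Iterable[SignalMetrics]) -> list[SignalMetrics]:
    """Consensus signals outside excluded SOCs."""
    return [m for m in metrics if m.consensus and not m.excluded]


def metrics_frame(metrics: Sequence[SignalMetrics]) -> pd.DataFrame:
    """Tabulate screening output with stable column order (for TSV export)."""
    rows = []
    for m in metrics:
        rows.append({
            "event": m.event, "level": m.level, "soc": m.soc, "a": m.a,
            "b": m.table.b, "c": m.table.c, "d": m.table.d,
            "ror": m.ror, "ror_ci_low": m.ror_ci_low,
            "ror_ci_high": m.ror_ci_high,
            "prr": m.prr, "chi2": m.chi2,
            "ic": m.ic, "ic025": m.ic025,
            "ebgm": m.ebgm, "ebgm05": m.ebgm05,
            "ror_pos": m.ror_pos, "prr_pos": m.prr_pos,
            "bcpnn_pos": m.bcpnn_pos, "mgps_pos": m.mgps_pos,
            "min_count_ok": m.min_count_ok,
            "consensus": m.consensus, "excluded": m.excluded,
        })
    return pd.DataFrame(rows)
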