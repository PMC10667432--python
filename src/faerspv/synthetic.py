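"""Synthetic FAERS-like quarterly data with known ground truth.

Real FAERS quarters are large downloads and carry no ground truth, so every
pipeline stage here is exercised against a generator that emulates the
relational structure of the database: reports keyed by PRIMARYID/CASEID,
drug rows with role codes, PT-coded events, therapy start dates, outcome
codes, duplicate report versions, a deleted-case list, and partially
missing or truncated dates.

Generative model (all randomness from one seeded ``numpy`` Generator):

* Each report takes the target drug with probability ``target_prevalence``
  (role PS) and otherwise one background drug.
* Background PT frequencies are a Dirichlet draw over ``n_background_pts``
  terms, so rare events and zero cells occur naturally. Planted signal PTs
  are assigned the median-rank probability of that draw, so recovery tests
  measure the planted relative rate rather than the luck of a rare
  background draw.
* A report records ``1 + Poisson(lambda)`` event draws from the PT
  multinomial; for target reports the planted PTs' probabilities are
  multiplied by their relative rate R and renormalized. Duplicate draws
  within a report collapse, as in real REAC tables.
* Therapy starts fall uniformly in the study window; the onset delay is
  log-normal (median ``exp(tto_mu)`` days), and EVENT_DT = START_DT +
  delay. FDA_DT follows the event by a short reporting lag. Missing and
  month-truncated dates are then injected at configurable rates.
* A fraction of cases is re-emitted as a later report version (higher
  PRIMARYID, later FDA_DT; a sub-fraction keeps an identical FDA_DT to
  exercise the PRIMARYID tie-break), and a fraction of CASEIDs goes on the
  deleted list.

The defaults model a cohort like the motivating use case: 50,000 reports,
2% target prevalence, three planted PTs at relative rate 10, ~85% female,
~89% serious, and date missingness leaving roughly 40% of target reports
with a computable time to onset.
"""

from __future__ import annotations

import dataclasses
import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from . import _dates
from .ingest import MeddraMap, RawTables, write_quarter
from .signals import ContingencyTable

TARGET_DRUGNAME = "TRODELVY"
TARGET_PROD_AI = "SACITUZUMAB GOVITECAN-HZIY"
TARGET_PATTERNS = ("sacituzumab govitecan", "trodelvy")


@dataclasses.dataclass
class SyntheticConfig:
    """Ground-truth generative parameters."""

    n_reports: int = 50_000
    n_background_drugs: int = 50
    n_background_pts: int = 200
    n_socs: int = 10
    dirichlet_concentration: float = 0.5
    target_prevalence: float = 0.02
    #: (PT name, relative reporting rate R) pairs; R=1 plants nothing.
    planted_signals: tuple[tuple[str, float], ...] = (
        ("PT_0010", 10.0), ("PT_0020", 10.0), ("PT_0030", 10.0))
    events_per_report_lambda: float = 2.0
    duplicate_fraction: float = 0.10
    duplicate_tie_fraction: float = 0.10
    deleted_fraction: float = 0.02
    missing_start_fraction: float = 0.35
    partial_start_fraction: float = 0.05
    missing_event_fraction: float = 0.25
    partial_event_fraction: float = 0.05
    sex_probs: tuple[float, float, float] = (0.854, 0.088, 0.058)  # F, M, missing
    age_mean: float = 56.0
    age_sd: float = 14.0
    missing_age_fraction: float = 0.51
    countries: tuple[str, ...] = ("US", "FR", "CA", "DE", "IT", "GB", "JP")
    country_probs: tuple[float, ...] = (0.36, 0.19, 0.12, 0.04, 0.04, 0.15, 0.10)
    occupations: tuple[str, ...] = ("MD", "PH", "CN", "")
    occupation_probs: tuple[float, ...] = (0.52, 0.36, 0.115, 0.005)
    serious_fraction: float = 0.89
    outcome_codes: tuple[str, ...] = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")
    outcome_probs: tuple[float, ...] = (0.21, 0.04, 0.24, 0.01, 0.002, 0.001,
                                        0.497)
    second_outcome_fraction: float = 0.3
    tto_mu: float = 2.64    # log-days; median exp(2.64) ~ 14 days
    tto_sigma: float = 1.49
    window_start: str = "20200401"
    window_end: str = "20221231"
    seed: int = 0

    def __post_init__(self):
        for name in ("target_prevalence", "duplicate_fraction",
                     "deleted_fraction", "missing_start_fraction",
                     "partial_start_fraction", "missing_event_fraction",
                     "partial_event_fraction", "missing_age_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        pts = self.pt_universe()
        for pt, rate in self.planted_signals:
            if rate < 0:
                raise ValueError(f"relative rate must be >= 0 for {pt}")
            if pt not in pts:
                raise ValueError(f"planted PT {pt!r} not in PT universe")

    def pt_universe(self) -> list[str]:
        return [f"PT_{i:04d}" for i in range(self.n_background_pts)]

    def soc_of_pt(self, i: int) -> str:
        return f"SOC_{i % self.n_socs:02d}"

    def meddra_map(self) -> MeddraMap:
        return MeddraMap({pt: self.soc_of_pt(i)
                          for i, pt in enumerate(self.pt_universe())})


@dataclasses.dataclass
class GroundTruth:
    """What the generator actually drew, for recovery tests."""

    config: SyntheticConfig
    background_probs: np.ndarray        # per-PT background multinomial
    target_probs: np.ndarray            # planted-reweighted multinomial
    is_target: np.ndarray               # per-report exposure flag
    table: pd.DataFrame                 # planted pt, R, p, expected a..d

    def expected_counts(self, pt: str) -> ContingencyTable:
        row = self.table[self.table["pt"] == pt]
        if row.empty:
            raise KeyError(pt)
        r = row.iloc[0]
        return ContingencyTable(r["expected_a"], r["expected_b"],
                                r["expected_c"], r["expected_d"])


def _include_prob(q: float | np.ndarray, lam: float):
    """P(PT appears in a report) when draws are 1+Poisson(lam) iid
    multinomial picks with probability q: 1 - (1-q) * exp(-lam * q)."""
    return 1.0 - (1.0 - q) * np.exp(-lam * q)


def expected_table(config: SyntheticConfig, pt: str,
                   background_probs: np.ndarray | None = None) -> ContingencyTable:
    """Closed-form expected a, b, c, d for one PT under the model.

    With realized ``background_probs`` the expectation conditions on the
    Dirichlet draw; without, the symmetric mean 1/n_pts is used.
    """
    pts = config.pt_universe()
    if pt not in pts:
        raise KeyError(pt)
    idx = pts.index(pt)
    n_pts = config.n_background_pts
    p = (np.full(n_pts, 1.0 / n_pts) if background_probs is None
         else np.asarray(background_probs, dtype=float))
    rates = np.ones(n_pts)
    for name, r in config.planted_signals:
        rates[pts.index(name)] = r
    q_target = p * rates / float(np.sum(p * rates))

    lam = config.events_per_report_lambda
    n_eff = config.n_reports * (1 - config.deleted_fraction)
    n_t = n_eff * config.target_prevalence
    n_o = n_eff - n_t
    p_t = float(_include_prob(q_target[idx], lam))
    p_o = float(_include_prob(p[idx], lam))
    a, c = n_t * p_t, n_o * p_o
    return _float_table(a, n_t - a, c, n_o - c)


def _float_table(a, b, c, d):
    # Expected tables carry real-valued cells; bypass the integer dataclass
    # by constructing it directly (counts stay non-negative).
    t = ContingencyTable.__new__(ContingencyTable)
    object.__setattr__(t, "a", a)
    object.__setattr__(t, "b", b)
    object.__setattr__(t, "c", c)
    object.__setattr__(t, "d", d)
    return t


def _date_array(days_from_epoch: np.ndarray, epoch: datetime.date) -> np.ndarray:
    base = np.datetime64(epoch.isoformat())
    dt = base + days_from_epoch.astype("timedelta64[D]")
    return np.char.replace(np.datetime_as_string(dt, unit="D"), "-", "")


def generate(config: SyntheticConfig,
             out_dir: str | Path | None = None) -> tuple[RawTables, GroundTruth]:
    """Generate one synthetic quarter; optionally write the file set.

    When ``out_dir`` is given, the FAERS-dialect files, a DELETED list, the
    PT->SOC map (``meddra_map.tsv``) and the ground-truth table
    (``ground_truth.tsv``) are written there. Fixed seed implies
    byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    pts = np.array(config.pt_universe())
    n_pts = config.n_background_pts

    # Background PT frequencies; planted PTs take the median-rank mass.
    probs = rng.dirichlet(np.full(n_pts, config.dirichlet_concentration))
    planted_idx = [config.pt_universe().index(p)
                   for p, _ in config.planted_signals]
    if planted_idx:
        order = np.argsort(probs)
        median_ranks = [order[n_pts // 2 + k] for k in range(len(planted_idx))]
        for pi, mi in zip(planted_idx, median_ranks):
            probs[pi], probs[mi] = probs[mi], probs[pi]
    rates = np.ones(n_pts)
    for name, r in config.planted_signals:
        rates[config.pt_universe().index(name)] = r
    target_probs = probs * rates
    target_probs /= target_probs.sum()

    caseid = np.array([f"{6000000 + i}" for i in range(n)])
    primaryid = np.array([f"{6000000 + i}1" for i in range(n)])
    is_target = rng.random(n) < config.target_prevalence

    # --- events ------------------------------------------------------------
    k = 1 + rng.poisson(config.events_per_report_lambda, n)
    report_idx = np.repeat(np.arange(n), k)
    draws = np.empty(report_idx.size, dtype=np.int64)
    tgt_rows = is_target[report_idx]
    draws[~tgt_rows] = rng.choice(n_pts, size=int((~tgt_rows).sum()), p=probs)
    draws[tgt_rows] = rng.choice(n_pts, size=int(tgt_rows.sum()),
                                 p=target_probs)
    reac = (pd.DataFrame({"PRIMARYID": primaryid[report_idx],
                          "PT": pts[draws], "_r": report_idx})
            .drop_duplicates(["_r", "PT"]).drop(columns="_r")
            .reset_index(drop=True))

    # --- dates -------------------------------------------------------------
    epoch = _dates.to_date(config.window_start)
    window_days = (_dates.to_date(config.window_end) - epoch).days
    start_off = rng.integers(0, window_days + 1, n)
    delay = np.round(rng.lognormal(config.tto_mu, config.tto_sigma, n)
                     ).astype(np.int64)
    event_off = start_off + delay
    fda_off = event_off + rng.integers(1, 90, n)

    start_dt = _date_array(start_off, epoch)
    event_dt = _date_array(event_off, epoch)
    fda_dt = _date_array(fda_off, epoch)

    u = rng.random(n)
    start_missing = u < config.missing_start_fraction
    start_partial = (~start_missing) & (
        u < config.missing_start_fraction + config.partial_start_fraction)
    v = rng.random(n)
    event_missing = v < config.missing_event_fraction
    event_partial = (~event_missing) & (
        v < config.missing_event_fraction + config.partial_event_fraction)

    start_out = start_dt.copy()
    if start_partial.any():
        start_out[start_partial] = np.array(
            [s[:6] for s in start_dt[start_partial]])
    event_out = event_dt.copy()
    event_out[event_missing] = ""
    if event_partial.any():
        event_out[event_partial] = np.array(
            [s[:6] for s in event_dt[event_partial]])

    # --- demographics ------------------------------------------------------
    sex = rng.choice(np.array(["F", "M", ""]), size=n,
                     p=np.array(config.sex_probs) / sum(config.sex_probs))
    age = np.round(rng.normal(config.age_mean, config.age_sd, n)).clip(18, 95)
    age_str = age.astype(int).astype(str)
    age_missing = rng.random(n) < config.missing_age_fraction
    age_str[age_missing] = ""
    age_cod = np.where(age_missing, "", "YR")
    country = rng.choice(np.array(config.countries), size=n,
                         p=np.array(config.country_probs)
                         / sum(config.country_probs))
    occp = rng.choice(np.array(config.occupations), size=n,
                      p=np.array(config.occupation_probs)
                      / sum(config.occupation_probs))

    demo = pd.DataFrame({
        "PRIMARYID": primaryid, "CASEID": caseid, "FDA_DT": fda_dt,
        "EVENT_DT": event_out, "AGE": age_str, "AGE_COD": age_cod,
        "SEX": sex, "OCCP_COD": occp, "REPORTER_COUNTRY": country,
        "OCCR_COUNTRY": country,
    })

    # --- drugs / therapy / indications ------------------------------------
    bg_drug = rng.integers(0, config.n_background_drugs, n)
    drugname = np.where(is_target, TARGET_DRUGNAME,
                        np.char.add("DRUG_", np.char.zfill(
                            bg_drug.astype(str), 3)))
    prod_ai = np.where(is_target, TARGET_PROD_AI,
                       np.char.add("INGREDIENT_", np.char.zfill(
                           bg_drug.astype(str), 3)))
    drug = pd.DataFrame({
        "PRIMARYID": primaryid, "DRUG_SEQ": "1", "ROLE_COD": "PS",
        "DRUGNAME": drugname, "PROD_AI": prod_ai,
    })
    ther = pd.DataFrame({
        "PRIMARYID": primaryid[~start_missing], "DSG_DRUG_SEQ": "1",
        "START_DT": start_out[~start_missing],
    })
    indi_pt = np.where(is_target,
                       rng.choice(np.array(["Triple negative breast cancer",
                                            "Breast cancer metastatic",
                                            "Transitional cell carcinoma"]),
                                  size=n, p=[0.7, 0.2, 0.1]),
                       "Product used for unknown indication")
    indi = pd.DataFrame({"PRIMARYID": primaryid, "INDI_DRUG_SEQ": "1",
                         "INDI_PT": indi_pt})

    # --- outcomes ----------------------------------------------------------
    serious = rng.random(n) < config.serious_fraction
    oc_probs = np.array(config.outcome_probs) / sum(config.outcome_probs)
    first = rng.choice(np.array(config.outcome_codes), size=n, p=oc_probs)
    second = rng.choice(np.array(config.outcome_codes), size=n, p=oc_probs)
    two = serious & (rng.random(n) < config.second_outcome_fraction) \
        & (first != second)
    outc = pd.concat([
        pd.DataFrame({"PRIMARYID": primaryid[serious],
                      "OUTC_COD": first[serious]}),
        pd.DataFrame({"PRIMARYID": primaryid[two], "OUTC_COD": second[two]}),
    ], ignore_index=True).sort_values("PRIMARYID",
                                      kind="mergesort").reset_index(drop=True)

    # --- duplicate versions ------------------------------------------------
    dup = rng.random(n) < config.duplicate_fraction
    tie = dup & (rng.random(n) < config.duplicate_tie_fraction)
    dup_idx = np.flatnonzero(dup)
    if dup_idx.size:
        dup_pid = np.array([f"{6000000 + i}2" for i in dup_idx])
        dup_fda_off = fda_off[dup_idx] + np.where(
            tie[dup_idx], 0, rng.integers(1, 30, dup_idx.size))
        dup_demo = demo.iloc[dup_idx].copy()
        dup_demo["PRIMARYID"] = dup_pid
        dup_demo["FDA_DT"] = _date_array(dup_fda_off, epoch)
        demo = pd.concat([demo, dup_demo], ignore_index=True)
        remap = dict(zip(primaryid[dup_idx], dup_pid))
        for name, df in (("drug", drug), ("reac", reac), ("ther", ther),
                         ("outc", outc), ("indi", indi)):
            extra = df[df["PRIMARYID"].isin(remap)].copy()
            extra["PRIMARYID"] = extra["PRIMARYID"].map(remap)
            if name == "drug":
                drug = pd.concat([drug, extra], ignore_index=True)
            elif name == "reac":
                reac = pd.concat([reac, extra], ignore_index=True)
            elif name == "ther":
                ther = pd.concat([ther, extra], ignore_index=True)
            elif name == "outc":
                outc = pd.concat([outc, extra], ignore_index=True)
            else:
                indi = pd.concat([indi, extra], ignore_index=True)

    deleted = frozenset(caseid[rng.random(n) < config.deleted_fraction])

    raw = RawTables(demo=demo.astype(str), drug=drug.astype(str),
                    reac=reac.astype(str), ther=ther.astype(str),
                    outc=outc.astype(str), indi=indi.astype(str),
                    deleted=deleted)

    # --- ground truth ------------------------------------------------------
    gt_rows = []
    for name, r in config.planted_signals:
        t = expected_table(config, name, background_probs=probs)
        gt_rows.append({"pt": name, "relative_rate": r,
                        "background_p": probs[config.pt_universe().index(name)],
                        "expected_a": t.a, "expected_b": t.b,
                        "expected_c": t.c, "expected_d": t.d})
    truth = GroundTruth(config=config, background_probs=probs,
                        target_probs=target_probs, is_target=is_target,
                        table=pd.DataFrame(gt_rows, columns=[
                            "pt", "relative_rate", "background_p",
                            "expected_a", "expected_b", "expected_c",
                            "expected_d"]))

    if out_dir is not None:
        out_dir = Path(out_dir)
        write_quarter(raw, out_dir)
        map_lines = ["PT\tSOC"] + [
            f"{pt}\t{config.soc_of_pt(i)}"
            for i, pt in enumerate(config.pt_universe())]
        (out_dir / "meddra_map.tsv").write_text("\n".join(map_lines) + "\n")
        truth.table.to_csv(out_dir / "ground_truth.tsv", sep="\t",
                           index=False)
    return raw, truth
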