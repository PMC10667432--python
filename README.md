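# faerspv

Disproportionality signal detection and time-to-onset analysis for
FAERS-style spontaneous adverse-event reports.

Post-marketing drug safety surveillance screens a spontaneous-report
database — reports that link drugs to suspected adverse events (AEs) coded
as MedDRA Preferred Terms (PTs), without any exposure denominator — for
drug–event pairs reported disproportionately often. `faerspv` implements
the full screening pipeline for the FDA Adverse Event Reporting System's
quarterly ASCII distribution format: file ingest, deleted-report removal,
report-version deduplication, primary-suspect cohort construction, four
disproportionality algorithms with a consensus rule at PT and System Organ
Class (SOC) level, a Table-2-style descriptive summary, and time-to-onset
(TTO) analysis. A synthetic report generator with known ground truth makes
every stage testable without downloading FAERS.

It is written for pharmacoepidemiologists and pharmacovigilance analysts
who want a scriptable, deterministic alternative to spreadsheet pipelines.

## The statistics

Each drug–event pair is screened through its report-level 2×2 table
(a = reports with target drug and event, b = target drug only, c = event
only, d = neither; n = a+b+c+d):

- **ROR** = ad/bc, with 95% CI exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d));
- **PRR** = (a/(a+b))/(c/(c+d)), with the uncorrected Pearson
  χ² = (ad−bc)²·n/((a+b)(c+d)(a+c)(b+d));
- **BCPNN information component** IC = log₂(a·n/((a+b)(a+c))), with
  closed-form Beta-shrinkage moments E(IC), V(IC) and the lower bound
  IC025 = E(IC) − 2√V(IC);
- **EBGM** = a·n/((a+b)(a+c)) (the closed-form relative reporting ratio;
  note IC = log₂ EBGM identically), with EBGM05 its lower 95% bound.

A pair is a **consensus signal** when a ≥ 3 and simultaneously
ROR CI low > 1; PRR ≥ 2 with χ² ≥ 4; IC025 > 0; EBGM05 > 2. Zero cells get
no continuity correction: undefined estimates simply fail their criterion.

TTO is the calendar-day interval from therapy start (earliest
full-precision START_DT of the primary-suspect drug) to event onset
(EVENT_DT); reports with missing or partial dates or a start after the
event are excluded, each with an explicit reason.

## Worked example

```python
from faerspv import ContingencyTable, compute_metrics

table = ContingencyTable(a=120, b=880, c=700, d=47_300)
m = compute_metrics("Neutropenia", table)
```

Running `python examples/formula_walkthrough.py` prints:

```
table: a=120 b=880 c=700 d=47300 n=49000
ROR  =   9.21  (95% CI 7.51-11.31)  positive: True
PRR  =   8.23  (chi2 661.57)  positive: True
IC   =   2.84  (IC025 2.47)  positive: True
EBGM =   7.17  (EBGM05 5.84)  positive: True
consensus signal: True
```

The event appears in 12% of target-drug reports against 1.5% elsewhere;
all four lower bounds clear their thresholds, so the pair is flagged. The
other scripts in `examples/` walk through synthetic-data screening
(`simulate_and_screen.py`, which recovers exactly the three planted PTs),
time-to-onset analysis and the end-to-end file pipeline.

## Command line

```sh
faerspv simulate --seed 3 --n-reports 10000 --out sim_q1
faerspv run-all --quarters sim_q1 --drug-name "sacituzumab govitecan" \
    --drug-name trodelvy --meddra sim_q1/meddra_map.tsv --out results
```

`run-all` writes `table2.tsv`, `signals_soc.tsv`, `signals_pt.tsv`,
`tto.tsv` and a `run_log.json` with counts at every stage. Real FAERS
quarters use the same `$`-delimited layout, so pointing `--quarters` at a
downloaded quarter directory works unchanged; the PT→SOC mapping is
user-supplied because MedDRA is licensed.

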