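# Methods

## The screening problem

A spontaneous-report database records, per safety report, the drugs a
reporter suspected and the adverse events observed, coded as MedDRA
Preferred Terms (PTs). There is no denominator of drug exposure, so
incidence cannot be estimated; what can be screened is *disproportionality*
— whether a drug–event pair is reported more often than expected if drug
and event were independent across the database. `faerspv` implements that
screen for the FDA quarterly ASCII distribution format, together with the
preprocessing the format requires (deduplication of report versions,
removal of deleted cases, primary-suspect cohort definition) and
time-to-onset (TTO) summaries.

## Data model and preprocessing

**Counting unit.** Throughout, the unit is the deduplicated report, not
the drug–event row: a report contributes at most one count to each cell of
any 2×2 table, and a report with several PTs inside one SOC counts once at
SOC level. A report with k distinct PTs does contribute to k PT-level
tables.

**Deduplication.** FAERS re-publishes a case (CASEID) under new report
versions (PRIMARYID) as follow-up arrives. Within each CASEID the version
with the latest FDA receipt date (FDA_DT) is kept; ties are broken by the
numerically highest PRIMARYID. Rows with a missing CASEID cannot be linked
and are kept as singletons, counted. The operation is idempotent and is
tested against a brute-force group-by oracle.

**Exposure definition.** A report is target-exposed iff at least one drug
row matches a user-supplied name pattern (case-insensitive substring over
DRUGNAME and PROD_AI — substring rather than exact match so suffixed
biologic names like "-hziy" and free-text noise still match) *and* that
row's role code is PS (primary suspect). Secondary-suspect, concomitant
and interacting rows never confer exposure.

**Dates.** FAERS dates are digit strings of length 8, 6 or 4. Partial
dates are retained with their precision, never padded: the TTO stage must
exclude them, and padding would silently convert a month-precision date
into a fabricated day. Malformed dates are blanked and counted per file.

**Seriousness.** A report is serious iff it carries any outcome code
(DE, LT, HO, DS, CA, RI, OT). Codes are tallied individually; a report may
carry several, so outcome tallies may exceed the serious-report count.
Unknown codes are tallied under "unknown" and still mark the report
serious.

**Age.** AGE is harmonized to years via AGE_COD (YR as-is, MON/12,
WK/52.14, DY/365.25); the DEC decade code and unknown codes yield a
missing age rather than a guess. Age bands: <18, 18–<45, 45–<65, ≥65,
unknown.

**Percentages.** Descriptive-table percentages use the full cohort as
denominator (not the non-missing subtotal) and round half-up at two
decimals — the only convention that reproduces printed numerator/total
pairs in published tables of this kind.

## Disproportionality algorithms

All four algorithms are deterministic functions of one 2×2 table
(a, b, c, d; n = a+b+c+d).

- **ROR** = ad/bc; 95% CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
- **PRR** = (a/(a+b))/(c/(c+d)); χ² is the uncorrected Pearson statistic
  (ad−bc)²·n/((a+b)(c+d)(a+c)(b+d)). No Yates correction.
- **BCPNN.** Point IC = log₂(a·n/((a+b)(a+c))). Shrinkage moments, with
  priors γ₁₁=1, α=β=2, α₁=β₁=1 (the standard published two-way choice,
  configurable via `BcpnnPriors`):

      γ     = γ₁₁ (n+α)(n+β) / ((a+b+α₁)(a+c+β₁))
      E(IC) = log₂[ (a+γ₁₁)(n+α)(n+β) / ((n+γ)(a+b+α₁)(a+c+β₁)) ]
      V(IC) = (1/ln2)² [ (n−a+γ−γ₁₁)/((a+γ₁₁)(1+n+γ))
                       + (n−(a+b)+α−α₁)/((a+b+α₁)(1+n+α))
                       + (n−(a+c)+β−β₁)/((a+c+β₁)(1+n+β)) ]
      IC025 = E(IC) − 2√V(IC)

  IC025 is the closed-form normal-approximation lower bound, not a
  posterior quantile from sampling. E(IC) and IC025 remain defined at
  a = 0; the point IC does not.
- **EBGM** = a·n/((a+b)(a+c)) — the closed-form relative reporting ratio —
  with EBGM05/95 = exp(ln EBGM ∓ 1.96·√(1/a+1/b+1/c+1/d)). This is *not*
  the DuMouchel gamma-Poisson EM shrinker that the MGPS name usually
  denotes; the closed form is used deliberately, and it makes
  IC = log₂(EBGM) an exact identity (property-tested).

**Zero cells.** No Haldane/continuity correction is applied anywhere. An
estimate or bound that is undefined on the raw table is returned as NaN
and fails its criterion; a correction is not silently substituted.

**Consensus rule.** A pair is a signal iff a ≥ 3 and ROR CI low > 1 and
PRR ≥ 2 with χ² ≥ 4 and IC025 > 0 and EBGM05 > 2. All thresholds live in
`Thresholds` and are CLI-overridable; overrides are logged so non-default
runs are self-documenting. For any table with positive margins,
ad > bc ⟺ ROR > 1 ⟺ PRR > 1 ⟺ EBGM > 1 ⟺ IC > 0, so the four
algorithms share one null crossing and differ in their uncertainty
penalties — the consensus rule is effectively an intersection of four
lower-bound criteria of different stringency.

**SOC exclusions.** SOCs dominated by indication or handling artefacts
(e.g. neoplasm progression, product issues) can be excluded from the
consensus report; excluded events are retained in the raw output with an
`excluded` flag, never dropped silently. PTs absent from the user-supplied
PT→SOC map surface under the pseudo-SOC `UNMAPPED`.

## Time to onset

Onset = EVENT_DT − START_DT in calendar days, where START_DT is the
earliest full-precision start among the matched primary-suspect drug rows
(earliest, because the first administration defines exposure start when
several therapy episodes exist). Exclusion reasons: `missing_start` (no
start row at all), `missing_event`, `partial_date` (either date below day
precision), `negative_interval` (start after event). When several reasons
co-occur they apply in that order of precedence, so every target report
lands in exactly one bucket and the partition sums to the cohort size.
Day 0 is a valid onset. Quartiles use linear interpolation between order
statistics (fractional published quartiles such as 0.50 rule out
nearest-rank; the method is configurable). Day bins are 0–30, 31–90,
91–180, 181–360, >360, bounds inclusive. The overall summary uses one
observation per report; the per-PT table uses one observation per
(report, PT) pair.

## Synthetic data generator

The generator emulates what the pipeline consumes: DEMO/DRUG/REAC/THER/
OUTC/INDI files in the `$`-delimited dialect, duplicate report versions
(always later FDA_DT, with a 10% sub-fraction of exact FDA_DT ties to
exercise the PRIMARYID tie-break), a deleted-case list, a PT→SOC map, and
a ground-truth table. All randomness comes from a single seeded generator;
a fixed seed gives byte-identical files.

Defaults model a realistic screening scenario: 50,000 reports, 2% target
prevalence, 200 background PTs with Dirichlet(0.5) frequencies (so rare
events and zero cells occur), 1+Poisson(2) events per report, three PTs
planted at relative draw rate R = 10, ~85% female, ~89% serious, ~51%
missing age, and date missingness leaving roughly 40% of target reports
with a computable onset; onset delays are log-normal with median ≈ 14
days (μ = 2.64, σ = 1.49). Planted PTs are assigned the median-rank
probability of the Dirichlet draw, so recovery tests measure the planted
effect rather than the luck of a rare background draw.

`expected_table` gives the closed-form expected 2×2 cells: with draw
probability q, a report includes the PT with probability
1 − (1−q)·e^(−λq), evaluated for the target-reweighted and background
multinomials respectively.

**What EBGM recovers.** The planted R multiplies a *draw* probability.
Per-report inclusion is concave in the draw probability (≈3 events per
report), the reweighting renormalizes the other PTs, and the target's
excess also inflates the (a+c) margin; together these attenuate the
expected EBGM for R = 10 to ≈ 7.3–8.5 at 2% prevalence. This is a
property of the statistic and the generative mechanism, not an estimation
error, so recovery tests compare observed EBGM to the generator's own
closed-form expectation (within ±15% at a ≥ 50) rather than to R.

**What the generator does not emulate:** drug co-prescription
correlation, free-text drug-name misspellings, reporting trends over
time, within-SOC PT correlation, and event-dependent seriousness. Passing
tests therefore demonstrate correctness of the pipeline's logic and the
statistical behaviour of the algorithms under a known model — not that
any particular real-world signal is causal or that real FAERS data meet
the model's independence assumptions.

## Problem sizes and numerical choices

The test suite screens twenty seeded 50,000-report replicates for the
signal-recovery property and 2,000 multinomial replicates for ROR CI
coverage; the acceptance script uses ten 50,000-report replicates and the
same coverage settings — sizes chosen so Monte-Carlo error is small
relative to the margins being tested while a full run stays in the
minutes range on one CPU. Formula agreement is checked on 1,000 random
tables against independent reference computations (statsmodels odds
ratio, scipy uncorrected χ², exact-rational re-evaluation of the BCPNN
moments) at 1e-10 relative tolerance. Output orderings break ties
lexicographically; file and table orderings are deterministic, so reruns
diff clean.

## Known limitations

- EBGM is the closed-form relative reporting ratio, not the EM-fitted
  gamma-mixture shrinker; for very small a it shrinks less than a true
  MGPS would, which the a ≥ 3 rule only partly offsets.
- No stratification or adjustment (age, sex, year) and no
  multiple-testing correction beyond the four-way consensus — matching
  standard first-pass screening practice, but confounding by indication
  remains.
- Key-based deduplication only; probabilistic record linkage of
  re-entered cases with new CASEIDs is out of scope.
- The reader supports the quarterly ASCII dialect; acquisition of real
  quarters (and a licensed MedDRA mapping) is the user's concern.
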