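"""Compute all four disproportionality algorithms on one 2x2 table.

The table counts deduplicated reports: a = target drug with the event of
interest, b = target drug without it, c = other drugs with it, d = other
drugs without it. A consensus signal must clear all four criteria at once:
ROR 95% CI low > 1; PRR >= 2 with chi2 >= 4; IC025 > 0; EBGM05 > 2; and
a >= 3 reports.
"""

from faerspv import ContingencyTable, compute_metrics

# A strong haematological signal: 120 of 1,000 target-drug reports mention
# the event, versus 700 of 48,000 reports for all other drugs.
table = ContingencyTable(a=120, b=880, c=700, d=47_300)
m = compute_metrics("Neutropenia", table)

print(f"table: a={table.a} b={table.b} c={table.c} d={table.d} n={table.n}")
print(f"ROR  = {m.ror:6.2f}  (95% CI {m.ror_ci_low:.2f}-{m.ror_ci_high:.2f})"
      f"  positive: {m.ror_pos}")
print(f"PRR  = {m.prr:6.2f}  (chi2 {m.chi2:.2f})  positive: {m.prr_pos}")
print(f"IC   = {m.ic:6.2f}  (IC025 {m.ic025:.2f})  positive: {m.bcpnn_pos}")
print(f"EBGM = {m.ebgm:6.2f}  (EBGM05 {m.ebgm05:.2f})  positive: {m.mgps_pos}")
print(f"consensus signal: {m.consensus}")
# ROR ~9.2 means the odds of this event among target-drug reports are ~9x
# the odds among all other reports; all four lower bounds clear their
# thresholds, so the pair is flagged for clinical review.
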