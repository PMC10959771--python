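"""Derive lines of therapy from a hand-built dispensing stream.

Demonstrates the grace-period exposure merge and the line-advancing rules:
an AI agent swap does not advance the line (exchangeability), while a
switch to chemotherapy does.
"""

import datetime as dt

from claimlines import (
    DispensingEvent,
    build_exposure_intervals,
    derive_lines,
    load_code_rules,
)

rules = load_code_rules()
base = dt.date(2018, 1, 1)
day = lambda n: base + dt.timedelta(days=n)

refills = []
for d in range(0, 301, 30):  # palbociclib + letrozole, monthly refills
    refills.append(DispensingEvent("P1", day(d), "palbociclib", 30))
for d in range(0, 151, 30):  # letrozole swapped for exemestane at month ~6
    refills.append(DispensingEvent("P1", day(d), "letrozole", 30))
for d in range(180, 301, 30):
    refills.append(DispensingEvent("P1", day(d), "exemestane", 30))
for d in range(360, 451, 30):  # chemotherapy starts within the grace window
    refills.append(DispensingEvent("P1", day(d), "chemotherapy", 30))

intervals = build_exposure_intervals(refills, rules, grace_days=60)
print("continuous exposure intervals (class, start, end):")
for iv in intervals:
    print(f"  {iv.drug_class.value:<8} {iv.start} .. {iv.end}")

lines = derive_lines(intervals, index_date=day(0), death_date=None,
                     cutoff=dt.date(2019, 12, 31), patient_id="P1")
print("\nderived lines of therapy:")
for line in lines:
    print(f"  line {line.ordinal}: {line.regimen_label:<20} "
          f"{line.start} .. {line.end}  ends by {line.end_reason.value}")

# Expected: one CDK46I+AI line (the AI-agent swap is exchangeable and the
# within-class gap is under the 60-day grace), ended by switch when
# chemotherapy starts, followed by a CHEMO line.
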