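"""Generate a synthetic claims set and inspect one patient's event streams.

The generator emulates a linked national claims extract: dated drug
dispensings, ICD-10 hospital diagnoses, demographics and death records.
"""

from claimlines import default_config, generate, planted_truth

config = default_config(n_patients=300, seed=42)
claims = generate(config)
truth = planted_truth(config)

print(f"patients generated: {len(claims.bundles)}")
print(f"planted first-line duration medians (months): "
      f"AI={truth.median_line1_duration_months['AI']:.1f}, "
      f"FULV={truth.median_line1_duration_months['FULV']:.1f}")

patient = claims.bundles[0]
print(f"\npatient {patient.patient_id}: sex={patient.sex}, "
      f"born {patient.birth_date}, death={patient.death_date}")
print("first dispensings (date, drug, days supplied):")
for ev in patient.dispensings[:6]:
    print(f"  {ev.date}  {ev.drug:<14} {ev.days_supply}")
print("diagnoses (date, ICD-10):")
for ev in patient.diagnoses[:6]:
    print(f"  {ev.date}  {ev.icd10}")

# The refill cadence (~30 days) and the metastasis/comorbidity codes are what
# the phenotyping and line-derivation steps consume downstream.
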