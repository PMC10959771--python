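"""Phenotype an mBC cohort from coded claims and print the attrition table.

Shows the index-date rule (first mBC-defining drug or secondary-malignancy
code), the ascertainment algorithm, and the eligibility cascade.
"""

import datetime as dt

from claimlines import (
    default_config,
    find_index_date,
    generate,
    load_code_rules,
    meets_mbc_algorithm,
    build_cohort,
)

rules = load_code_rules()
claims = generate(default_config(n_patients=500, seed=7))

# single-patient view
bundle = claims.bundles[0]
print(f"{bundle.patient_id}: index date = {find_index_date(bundle, rules)}, "
      f"meets mBC algorithm = {meets_mbc_algorithm(bundle, rules)}")

records, lines, attrition = build_cohort(
    list(claims.bundles), rules, procedures=claims.procedures
)
print("\nattrition (reasons partition the input population):")
for step, count in attrition.items():
    print(f"  {step:<40} {count}")

by_arm = {}
for r in records:
    by_arm[r.arm] = by_arm.get(r.arm, 0) + 1
print(f"\ncohort: {len(records)} patients, arms: {by_arm}")
r = records[0]
print(f"example record: age {r.age_at_index}, {r.menopausal_status}-menopausal, "
      f"endocrine {r.endocrine_status}, visceral={r.visceral}, "
      f"Charlson category {r.charlson_category}")
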