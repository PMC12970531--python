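"""Generate a synthetic hemodialysis cohort and write it as a table.

The default group specifications reproduce the study population's
structure: 346 functional iron deficit, 156 absolute, 145 IV-iron trial
candidates and 236 suspected severe hyperparathyroidism patients (883
total), with ineligible padding records to exercise the exclusion path.
"""

from collections import Counter

from anemia_cdss import (
    default_group_specs,
    generate_cohort,
    inject_ineligible,
    write_cohort_table,
)

records = generate_cohort(default_group_specs(), seed=7)
augmented = inject_ineligible(records, n_minor=5, n_high_hb=5, n_incomplete=5,
                              seed=8)

print("group sizes:", dict(Counter(
    r.true_label.value for r in records
)))
print(f"total records after padding: {len(augmented)} "
      f"({len(augmented) - len(records)} ineligible)")

write_cohort_table([r.panel for r in augmented], "scratch_cohort.csv")
print("wrote scratch_cohort.csv")
# Each record's labs are drawn from truncated normals confined to its
# group's rule region, so classification recovers every true label.
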