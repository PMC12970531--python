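"""Full pipeline: simulate, ingest, filter, classify, summarize, export.

Prints the ingest funnel, the per-group composition, and the
functional-deficit/high-PTH co-occurrence, then writes the Table-1,
long-format and manifest reports.
"""

import io

from anemia_cdss import (
    apply_filters,
    build_guideline_ruleset,
    classify_cohort,
    default_group_specs,
    export_reports,
    first_record_per_patient,
    generate_cohort,
    inject_ineligible,
    read_cohort_table,
    summarize_cohort,
    write_cohort_table,
)

ruleset = build_guideline_ruleset()
records = generate_cohort(default_group_specs(), seed=1)
augmented = inject_ineligible(records, 5, 5, 5, seed=2)

# round-trip through the delimited format, as a LIS export would arrive
buffer = io.StringIO()
write_cohort_table([r.panel for r in augmented], buffer)
buffer.seek(0)
panels, issues = read_cohort_table(buffer)
panels = first_record_per_patient(panels)
eligible, report = apply_filters(panels)
print(f"funnel: {report.n_input} in -> {report.n_eligible} eligible, "
      f"exclusions {report.exclusions}")

results = classify_cohort(eligible, ruleset)
summary = summarize_cohort(eligible, results)
for row in summary.groups:
    if row.n:
        print(f"  {row.label.value:<28} n={row.n:<4} "
              f"{row.pct_of_cohort:.1f} % of cohort")
cooc = summary.cooccurrence
print(f"functional-deficit patients with PTH > 800 pg/ml: "
      f"{cooc.n} ({cooc.pct_of_functional:.1f} % of the functional group)")

paths = export_reports(summary, eligible, results, "scratch_reports",
                       manifest_extra={"seed": 1})
print("reports:", ", ".join(str(p) for p in paths.values()))
# The group percentages (39.2 / 17.7 / 16.4 / 26.7 %) and the 9.5 %
# co-occurrence are exact because the generator plants those group sizes.
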