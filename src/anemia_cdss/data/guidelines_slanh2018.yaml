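
# Guideline-derived ruleset for anemia classification in prevalent
# hemodialysis (SLANH 2018, complemented by KDIGO 2012 / NICE 2015).
# Thresholds and their strict/non-strict boundary semantics are data, not
# code, so they stay auditable.  Units: age years, hemoglobin g/dl,
# ferritin ng/ml, tsat %, pth pg/ml.
name: guidelines_slanh2018
version: "2018.1"
rules:
  - rule_id: absolute_iron_deficit
    label: ABSOLUTE_IRON_DEFICIT
    tier: 0
    recommendation: >-
      Absolute iron deficit (depleted stores): direct repletion with
      intravenous iron is suggested before any ESA dose adjustment.
    predicates:
      - {analyte: age, comparator: ge, threshold: 18}
      - {analyte: hemoglobin, comparator: lt, threshold: 12}
      - {analyte: tsat, comparator: lt, threshold: 20}
      - {analyte: ferritin, comparator: lt, threshold: 200}
  - rule_id: functional_iron_deficit
    label: FUNCTIONAL_IRON_DEFICIT
    tier: 0
    recommendation: >-
      Functional iron deficit (adequate stores, impaired mobilization,
      pattern of inflammatory iron sequestration): re-evaluate the
      inflammatory state and review the iron supplementation strategy
      and ESA dosing.
    predicates:
      - {analyte: age, comparator: ge, threshold: 18}
      - {analyte: hemoglobin, comparator: lt, threshold: 12}
      - {analyte: tsat, comparator: lt, threshold: 20}
      - {analyte: ferritin, comparator: ge, threshold: 200}
      - {analyte: ferritin, comparator: le, threshold: 500}
  - rule_id: iv_iron_trial_candidate
    label: IV_IRON_TRIAL_CANDIDATE
    tier: 0
    recommendation: >-
      Intermediate iron profile: a monitored therapeutic trial of
      intravenous iron is suggested, with follow-up of the hemoglobin
      response.
    predicates:
      - {analyte: age, comparator: ge, threshold: 18}
      - {analyte: hemoglobin, comparator: lt, threshold: 12}
      - {analyte: tsat, comparator: ge, threshold: 20}
      - {analyte: tsat, comparator: le, threshold: 30}
      - {analyte: ferritin, comparator: ge, threshold: 200}
      - {analyte: ferritin, comparator: le, threshold: 500}
  - rule_id: severe_shpt_suspect
    label: SEVERE_SHPT_SUSPECT
    tier: 1
    recommendation: >-
      Suspected severe secondary hyperparathyroidism: work-up of mineral
      and bone disorder is suggested; consider hyperparathyroidism as a
      cause of ESA hypo-responsiveness.
    predicates:
      - {analyte: pth, comparator: gt, threshold: 800}
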