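# Methods

## The classification model

The package implements a flat, prioritized rule engine over a single
patient's laboratory panel.  Each rule is a conjunction of crisp
threshold predicates (`analyte comparator threshold`, comparator ∈
{<, ≤, ≥, >}); comparisons are exact floating-point comparisons with no
epsilon, because the underlying clinical logic is stated with crisp
inequalities and the engine's job is to apply it verbatim.  Rules carry
an integer tier: tier 0 holds the three iron-profile rules, tier 1 the
PTH rule.  Tiers are evaluated in ascending order; the first tier in
which a rule fires supplies the label, and later-tier firings become
combined alerts rather than labels.

This precedence — iron label wins, elevated PTH on top of an iron label
becomes an `SHPT_COMBINED` alert — is a design reconstruction, not an
explicitly stated procedure.  It is the only ordering consistent with
the reported cohort: the four group counts (346 + 156 + 145 + 236) sum
exactly to the 883-patient cohort, implying mutually exclusive groups,
while a stated subset of 33 high-PTH patients sits *inside* the
functional-deficit group.  Equivalently, the SHPT group must consist of
patients for whom no iron rule fired.  How such patients' iron panels
looked (ferritin > 500 ng/ml? TSAT > 30 %?) is never described; the
synthetic generator picks one consistent realization (see below).

Patients matching no rule at all are labeled `UNCLASSIFIED` and kept
visible through every report; the source cohort's exact partition into
four groups suggests it contained none, but the pipeline must surface
rather than drop them (e.g. ferritin > 500 ng/ml with low TSAT and
normal PTH).

Two engine-level guarantees are tested as properties: determinism
(identical panel + ruleset ⇒ identical result) and totality (every
complete eligible panel receives exactly one of the five labels).
Same-tier disjointness of the shipped ruleset is checked two independent
ways: analytically, by pairwise interval intersection of the rules'
conjunctive regions (`validate_ruleset`), and by brute force on a
ferritin × TSAT grid (0–600 ng/ml step 0.5 × 0–40 % step 0.1) with
hard-coded region masks.

## Eligibility and completeness

Exclusion criteria are applied in fixed priority order: age < 18 years,
then hemoglobin ≥ 12 g/dl, then any of hemoglobin/ferritin/TSAT absent
(complete-case analysis; no value is ever imputed).  PTH is deliberately
never inspected by the filter: patients without a PTH measurement are
classifiable by the iron rules and simply cannot fire the PTH rule or
alert.

One boundary is formally ambiguous in the source material: the
exclusion criterion reads "greater than 12 g/dl" while the rule logic
requires Hb < 12.  A panel at exactly 12.0 could never classify, so the
filter excludes it (`hb_ge_12`); filter and rules stay consistent.  Age
is completed years ("años cumplidos"): fractional ages are floored.

Dialysis vintage (≥ 90 days, the "prevalent hemodialysis" criterion) is
not a laboratory variable and is assumed to be enforced upstream of the
ingested export.

## Ingestion

Delimited tables accept configurable separator and decimal mark
(Spanish-locale exports print "369,2"); unparseable or invalid rows
become per-row issues in the audit report, never crashes or defaults.
Deduplication keeps the earliest specimen date per patient, ties broken
by input order.  The funnel report satisfies a conservation invariant —
eligible + Σ exclusions = deduplicated input — enforced at construction.
HL7 support is a minimal v2 ORU^R01 subset (MSH/PID/OBR/OBX, one patient
per message, numeric OBX only), with observation codes mapped to
analytes through a configurable table defaulting to LOINC codes; the
parser is written in-package (plain pipe/caret splitting), sized to this
interface.

## The synthetic cohort generator

No patient-level data are deposited, so the generator emulates the
reported cohort structure directly; its defaults *are* the study
conditions:

- Group sizes 346 / 156 / 145 / 236 (functional, absolute, candidate,
  SHPT; 883 total), age means ± SD 58.5 ± 16.4 / 57.5 ± 15.3 /
  59.2 ± 16.8 / 47.5 ± 16.0 years, female proportions 43.6 / 39.1 /
  34.5 / 50.0 %.
- Lab means per group: Hb 10.4 / 10.2 / 10.7 g/dl, ferritin
  369.2 / 118.7 / 372.5 ng/ml, TSAT 14.1 / 11.3 / 23.6 %, and PTH mean
  1378.5 pg/ml for the SHPT group.
- Within the functional group exactly 33 records (9.5 %) carry PTH
  drawn above 800 pg/ml — the reported iron/PTH co-occurrence — while
  the remaining iron-group records leave PTH absent, mirroring a source
  table in which the iron groups have no PTH summary.

Values are drawn from truncated normal distributions whose bounds lie
strictly inside each group's rule region, with a small safety margin
(e.g. functional ferritin on [200.5, 499.5]); every truncation corner is
checked against the live ruleset at generation time (`SpecError` if it
escapes), which makes 100 % label recovery a structural guarantee rather
than a statistical one.  Ages come from a truncated normal bounded below
at 18 and floored to completed years; sex is Bernoulli; specimen dates
are uniform over the study year (2023).

Assumptions the source does not determine, fixed once as configuration:

- Lab-analyte SDs are not reported (only age SDs); defaults are
  plausible clinical spreads — Hb 1.0 g/dl, ferritin 80 ng/ml, TSAT 3 %,
  PTH 400 pg/ml.
- The distributional family (truncated normal) is a generator
  convenience; the source reports only means/SDs and medians/IQRs.
- The SHPT group's iron panel is drawn with ferritin in (505, 1000)
  ng/ml and TSAT < 20 %, placing it outside all three iron regions so
  the precedence reconstruction reproduces exclusive group sizes.  This
  is one consistent choice among several (high TSAT would also work).

Known discrepancy in the source, documented rather than repaired: the
summary table's row labels conflict with the running text (the n = 346
row is labeled as absolute deficit yet carries ferritin 369.2 ng/ml,
which matches the text's functional group, and the printed per-group row
order swaps the two deficit groups' demographics).  The generator
follows the running text.  Relatedly, the overall printed mean age
(54.5) and female percentage (43.5 %) are not exactly reconcilable with
the per-group values (weighted recomputation gives ≈ 55.5 years and
≈ 43.0 %); the pipeline reports what it computes and does not force
agreement.

What passing tests show — and don't: the synthetic cohort exercises
every pipeline stage and makes the group structure exactly recoverable,
but it has no measurement noise near rule boundaries, no
inflammation-biomarker correlation structure, no longitudinal repeats
beyond injected duplicates, and clean identifiers.  Performance on it
says nothing about classification accuracy on real LIS data.

## Descriptive statistics and reports

Means use the sample (n−1) SD; medians and IQR (Q3 − Q1) use the
linear-interpolation quantile convention (the source names the
statistics but no convention).  Internal values are full precision;
display rounding is one decimal for percentages and analyte means,
matching the source table.  A group with n = 0 keeps its row with
statistics marked absent ("-"); n = 1 marks the SD absent.  Report
rendering is locale-stable (always "." decimal, fixed column order), so
identical summaries produce byte-identical files.  The co-occurrence
statistic counts functional-deficit patients with PTH present and
strictly above the threshold (default 800 pg/ml), as a share of the
functional group.

## Problem sizes

Tests and the acceptance script run the pipeline at the full published
cohort size (883 records, plus 15 injected ineligible records), the
disjointness grid at 1,201 × 401 points, and the statistics oracle on
100 random small cohorts — the whole suite completes in a few seconds.

## Limitations

- The rule engine is a flat prioritized conjunction evaluator; it does
  not implement ripple-down exception-tree knowledge acquisition, which
  the production system it models uses for incremental refinement.
- TSAT is taken as reported, never computed from serum iron and TIBC.
- No inferential statistics, ESA/iron dosing logic, outcome evaluation,
  or figure rendering (the long-format export is boxplot-ready input for
  any plotting tool).
- HL7 v3/XML, live LIS connectivity and notification delivery are out of
  scope.
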