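"""Check that same-tier rule regions are mutually exclusive.

The three iron-profile rules must partition their patients: the
validator intersects each pair's conjunctive regions axis by axis and
reports any shared hyper-rectangle.  A deliberately perturbed ruleset
(absolute deficit extended to ferritin < 250 ng/ml) shows what an
authoring error looks like.
"""

from anemia_cdss import (
    Analyte,
    Predicate,
    Rule,
    RuleSet,
    build_guideline_ruleset,
    validate_ruleset,
)

ruleset = build_guideline_ruleset()
report = validate_ruleset(ruleset)
print(f"guideline ruleset: {report.pairs_checked} same-tier pairs checked, "
      f"{len(report.overlaps)} overlaps")

perturbed = []
for rule in ruleset:
    if rule.rule_id == "absolute_iron_deficit":
        preds = tuple(
            Predicate("ferritin", "lt", 250.0)
            if p.analyte is Analyte.FERRITIN else p
            for p in rule.predicates
        )
        rule = Rule(rule.rule_id, rule.label, preds, rule.tier,
                    rule.recommendation)
    perturbed.append(rule)

bad_report = validate_ruleset(RuleSet(perturbed))
for ov in bad_report.overlaps:
    region = ", ".join(f"{a.value} in {iv}" for a, iv in ov.region.items())
    print(f"perturbed ruleset overlap: {ov.rule_a} vs {ov.rule_b} on {region}")
# The overlap is exactly ferritin in [200, 250) with TSAT < 20 under
# anemia — patients there would satisfy two rules at once, which the
# classifier reports as a RulesetConflict.
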