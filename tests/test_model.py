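"""Rule engine: predicate semantics, conjunction, precedence, disjointness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anemia_cdss import (
    Analyte,
    Label,
    MissingAnalyte,
    Predicate,
    Rule,
    RuleSet,
    RulesetConflict,
    ValidationError,
    classify,
    evaluate_predicate,
    evaluate_rule,
    validate_ruleset,
)
from anemia_cdss.model import rule_region

from conftest import panel


class TestPanelValidation:
    def test_tsat_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            panel(tsat=140.0)

    def test_negative_lab_rejected(self):
        with pytest.raises(ValidationError):
            panel(ferritin=-1.0)

    def test_empty_patient_id_rejected(self):
        with pytest.raises(ValidationError):
            panel(pid="")

    def test_fractional_age_floored_to_completed_years(self):
        assert panel(age=17.9).age == 17

    def test_sex_spanish_tokens_parse(self):
        assert panel(sex="femenino").sex.value == "female"
        assert panel(sex="Masculino").sex.value == "male"


class TestEvaluatePredicate:
    def test_ferritin_450_is_ge_200(self):
        assert evaluate_predicate(panel(ferritin=450.0),
                                  Predicate("ferritin", "ge", 200.0))

    @pytest.mark.parametrize(
        "comparator,expected",
        # all four comparators at an exact boundary value: strict
        # inequalities exclude the boundary, non-strict include it
        [("lt", False), ("le", True), ("ge", True), ("gt", False)],
    )
    def test_boundary_semantics_exact(self, comparator, expected):
        assert (
            evaluate_predicate(panel(tsat=20.0), Predicate("tsat", comparator, 20.0))
            is expected
        )

    def test_hb_exactly_12_fails_strict_lt(self):
        assert not evaluate_predicate(
            panel(hemoglobin=12.0), Predicate("hemoglobin", "lt", 12.0)
        )

    def test_missing_analyte_raises_never_defaults(self):
        with pytest.raises(MissingAnalyte) as err:
            evaluate_predicate(panel(ferritin=None), Predicate("ferritin", "lt", 200))
        assert "ferritin" in str(err.value)


class TestEvaluateRule:
    def test_functional_profile_fires(self, ruleset):
        (rule,) = ruleset.by_label(Label.FUNCTIONAL_IRON_DEFICIT)
        assert evaluate_rule(
            panel(age=60, hemoglobin=10.5, ferritin=450, tsat=18), rule
        )

    def test_high_hb_fails_absolute(self, ruleset):
        (rule,) = ruleset.by_label(Label.ABSOLUTE_IRON_DEFICIT)
        assert not evaluate_rule(
            panel(age=60, hemoglobin=12.5, ferritin=100, tsat=10), rule
        )

    def test_interval_boundaries_match_printed_logic(self, ruleset):
        # ferritin exactly 200 belongs to the functional interval
        # (>= 200), never to absolute (< 200); tsat just under 20 stays
        # in the low-saturation branch
        p = panel(age=18, hemoglobin=11.99, ferritin=200.0, tsat=19.99)
        (functional,) = ruleset.by_label(Label.FUNCTIONAL_IRON_DEFICIT)
        (absolute,) = ruleset.by_label(Label.ABSOLUTE_IRON_DEFICIT)
        assert evaluate_rule(p, functional)
        assert not evaluate_rule(p, absolute)

    def test_missing_analyte_propagates(self, ruleset):
        (rule,) = ruleset.by_label(Label.ABSOLUTE_IRON_DEFICIT)
        with pytest.raises(MissingAnalyte):
            evaluate_rule(panel(hemoglobin=10.0, ferritin=None, tsat=10), rule)


class TestClassify:
    """The three in-text vignettes plus the precedence reconstruction."""

    def test_inflammatory_sequestration_profile_is_functional(self, ruleset):
        result = classify(panel(age=60, hemoglobin=10.5, ferritin=450, tsat=18),
                          ruleset)
        assert result.label is Label.FUNCTIONAL_IRON_DEFICIT

    def test_depleted_stores_profile_is_absolute(self, ruleset):
        result = classify(panel(age=60, hemoglobin=11.8, ferritin=120, tsat=14),
                          ruleset)
        assert result.label is Label.ABSOLUTE_IRON_DEFICIT

    def test_iron_label_with_high_pth_gains_combined_alert(self, ruleset):
        result = classify(
            panel(age=60, hemoglobin=10.0, ferritin=450, tsat=18, pth=900), ruleset
        )
        assert result.label is Label.FUNCTIONAL_IRON_DEFICIT
        assert [a.alert_code for a in result.alerts] == ["SHPT_COMBINED"]

    def test_no_iron_rule_and_high_pth_labels_shpt(self, ruleset):
        # brute-force check: ferritin 600 escapes every iron interval,
        # so only the PTH rule can fire
        p = panel(age=60, hemoglobin=10.0, ferritin=600, tsat=15, pth=850)
        for label in (Label.ABSOLUTE_IRON_DEFICIT, Label.FUNCTIONAL_IRON_DEFICIT,
                      Label.IV_IRON_TRIAL_CANDIDATE):
            (rule,) = ruleset.by_label(label)
            assert not evaluate_rule(p, rule)
        assert classify(p, ruleset).label is Label.SEVERE_SHPT_SUSPECT

    def test_no_rule_fires_yields_unclassified(self, ruleset):
        result = classify(panel(age=60, hemoglobin=10.0, ferritin=600, tsat=15),
                          ruleset)
        assert result.label is Label.UNCLASSIFIED
        assert not result.fired_rule_ids

    def test_absent_pth_never_errors_or_alerts(self, ruleset):
        result = classify(panel(age=60, hemoglobin=10.5, ferritin=450, tsat=18,
                                pth=None), ruleset)
        assert result.label is Label.FUNCTIONAL_IRON_DEFICIT
        assert not result.alerts

    def test_same_tier_double_fire_is_a_conflict(self):
        overlapping = RuleSet([
            Rule("a", Label.ABSOLUTE_IRON_DEFICIT,
                 (Predicate("ferritin", "lt", 300),), tier=0),
            Rule("b", Label.FUNCTIONAL_IRON_DEFICIT,
                 (Predicate("ferritin", "lt", 400),), tier=0),
        ])
        with pytest.raises(RulesetConflict):
            classify(panel(ferritin=100.0), overlapping)

    @given(
        hb=st.floats(0, 11.99),
        ferritin=st.floats(0, 1500),
        tsat=st.floats(0, 100),
        pth=st.one_of(st.none(), st.floats(0, 3000)),
        age=st.integers(18, 100),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_totality_and_determinism(self, hb, ferritin, tsat, pth, age):
        """Every complete eligible panel gets exactly one label, repeatably."""
        ruleset = _GUIDELINES
        p = panel(age=age, hemoglobin=hb, ferritin=ferritin, tsat=tsat, pth=pth)
        first = classify(p, ruleset)
        second = classify(p, ruleset)
        assert first.label in Label
        assert first == second
        if first.label is not Label.UNCLASSIFIED:
            assert first.fired_rule_ids


# hypothesis can't take a fixture argument; module-level singleton instead
from anemia_cdss import build_guideline_ruleset

_GUIDELINES = build_guideline_ruleset()


def _grid_memberships():
    """Independent grid oracle over ferritin x TSAT at eligible age/Hb.

    Region masks are hard-coded from the published classification logic,
    not derived from the engine: absolute = ferritin < 200 & TSAT < 20;
    functional = 200 <= ferritin <= 500 & TSAT < 20; candidate =
    200 <= ferritin <= 500 & 20 <= TSAT <= 30.
    """
    ferritin = np.arange(0.0, 600.0 + 1e-9, 0.5)
    tsat = np.arange(0.0, 40.0 + 1e-9, 0.1)
    F, T = np.meshgrid(ferritin, tsat, indexing="ij")
    absolute = (F < 200) & (T < 20)
    functional = (F >= 200) & (F <= 500) & (T < 20)
    candidate = (F >= 200) & (F <= 500) & (T >= 20) & (T <= 30)
    return F, T, np.stack([absolute, functional, candidate])


class TestValidateRuleset:
    def test_guideline_tier0_regions_are_disjoint_by_grid(self):
        """No ferritin x TSAT grid point belongs to two iron regions."""
        _, _, masks = _grid_memberships()
        assert (masks.sum(axis=0) <= 1).all()
        report = validate_ruleset(_GUIDELINES)
        assert report.is_disjoint
        assert report.pairs_checked == 3  # three tier-0 pairs, tier 1 has one rule

    def test_engine_agrees_with_grid_oracle_on_subsample(self, ruleset):
        F, T, masks = _grid_memberships()
        rules = [ruleset.by_label(l)[0] for l in
                 (Label.ABSOLUTE_IRON_DEFICIT, Label.FUNCTIONAL_IRON_DEFICIT,
                  Label.IV_IRON_TRIAL_CANDIDATE)]
        for i in range(0, F.shape[0], 97):
            for j in range(0, F.shape[1], 31):
                p = panel(age=30, hemoglobin=10.0,
                          ferritin=float(F[i, j]), tsat=float(T[i, j]))
                engine = [evaluate_rule(p, r) for r in rules]
                assert engine == list(masks[:, i, j])

    def test_single_rule_ruleset_has_no_pairs(self):
        rs = RuleSet([Rule("only", Label.SEVERE_SHPT_SUSPECT,
                           (Predicate("pth", "gt", 800),), tier=1)])
        report = validate_ruleset(rs)
        assert report.pairs_checked == 0 and report.is_disjoint

    def test_perturbed_absolute_rule_overlaps_functional(self, ruleset):
        """Raising the absolute ferritin cut to 250 creates a shared region."""
        perturbed_rules = []
        for rule in ruleset:
            if rule.rule_id == "absolute_iron_deficit":
                preds = tuple(
                    Predicate("ferritin", "lt", 250.0)
                    if p.analyte is Analyte.FERRITIN else p
                    for p in rule.predicates
                )
                rule = Rule(rule.rule_id, rule.label, preds, rule.tier,
                            rule.recommendation)
            perturbed_rules.append(rule)
        report = validate_ruleset(RuleSet(perturbed_rules))
        assert not report.is_disjoint
        (overlap,) = report.overlaps
        assert {overlap.rule_a, overlap.rule_b} == {
            "absolute_iron_deficit", "functional_iron_deficit"
        }
        shared = overlap.region[Analyte.FERRITIN]
        assert (shared.lower, shared.upper) == (200.0, 250.0)
        # grid oracle detects the same overlap: a point in [200, 250) x T<20
        # satisfies both perturbed-absolute and functional masks
        F, T, _ = _grid_memberships()
        both = ((F < 250) & (T < 20)) & ((F >= 200) & (F <= 500) & (T < 20))
        assert both.any()

    def test_rule_region_intervals_match_predicates(self, ruleset):
        (functional,) = ruleset.by_label(Label.FUNCTIONAL_IRON_DEFICIT)
        region = rule_region(functional)
        ferr = region[Analyte.FERRITIN]
        assert (ferr.lower, ferr.lower_closed) == (200.0, True)
        assert (ferr.upper, ferr.upper_closed) == (500.0, True)
        tsat = region[Analyte.TSAT]
        assert (tsat.upper, tsat.upper_closed) == (20.0, False)


class TestRulesetSerialization:
    def test_yaml_round_trip_is_identity(self, ruleset):
        assert RuleSet.from_yaml(ruleset.to_yaml()) == ruleset

    def test_duplicate_rule_ids_rejected(self):
        rule = Rule("dup", Label.SEVERE_SHPT_SUSPECT,
                    (Predicate("pth", "gt", 800),))
        with pytest.raises(ValidationError):
            RuleSet([rule, rule])

    def test_non_finite_threshold_rejected(self):
        with pytest.raises(ValidationError):
            Predicate("pth", "gt", float("inf"))
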