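"""The concrete guideline knowledge base: ruleset, eligibility, recommendations.

Encodes the SLANH-2018-derived classification used for anemia in
prevalent hemodialysis: under anemia (Hb < 12 g/dl, single cut-off for
both sexes) and adult age, the iron profile splits into absolute deficit
(ferritin < 200 ng/ml, TSAT < 20 %), functional deficit (ferritin
200–500 ng/ml, TSAT < 20 %) and candidates for a therapeutic IV-iron
trial (ferritin 200–500 ng/ml, TSAT 20–30 %); PTH > 800 pg/ml flags
suspected severe secondary hyperparathyroidism.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources

from .errors import NoRecommendation
from .model import Analyte, AnalytePanel, Label, RuleSet

__all__ = [
    "EligibilityStatus",
    "ExclusionReason",
    "EligibilityOutcome",
    "build_guideline_ruleset",
    "eligibility_filter",
    "recommendation_text",
    "GUIDELINE_RESOURCE",
]

GUIDELINE_RESOURCE = "guidelines_slanh2018.yaml"

#: analytes that must be present for a record to enter classification
KEY_ANALYTES = (Analyte.HEMOGLOBIN, Analyte.FERRITIN, Analyte.TSAT)

#: anemia definition, single cut-off for both sexes
ANEMIA_HB_CUTOFF = 12.0
ADULT_AGE = 18


class EligibilityStatus(str, enum.Enum):
    ELIGIBLE = "eligible"
    EXCLUDED = "excluded"


class ExclusionReason(str, enum.Enum):
    NONE = "none"
    AGE_LT_18 = "age_lt_18"
    HB_GE_12 = "hb_ge_12"
    INCOMPLETE_RECORD = "incomplete_record"


@dataclass(frozen=True)
class EligibilityOutcome:
    status: EligibilityStatus
    reason: ExclusionReason

    def __post_init__(self) -> None:
        eligible = self.status is EligibilityStatus.ELIGIBLE
        assert eligible == (self.reason is ExclusionReason.NONE)

    @property
    def eligible(self) -> bool:
        return self.status is EligibilityStatus.ELIGIBLE


def build_guideline_ruleset() -> RuleSet:
    """Load the shipped guideline ruleset.

    Four rules: the three mutually exclusive iron-profile rules in tier 0
    and the PTH > 800 pg/ml severe-hyperparathyroidism rule in tier 1.
    """
    text = (
        resources.files("anemia_cdss").joinpath("data", GUIDELINE_RESOURCE)
        .read_text(encoding="utf-8")
    )
    return RuleSet.from_yaml(text)


def eligibility_filter(panel: AnalytePanel) -> EligibilityOutcome:
    """Apply the cohort exclusion criteria to one panel.

    Checks, in fixed priority order: age < 18 years; hemoglobin >= 12
    g/dl (a panel at exactly 12.0 can never satisfy the anemia rules, so
    it is ineligible); any of hemoglobin/ferritin/TSAT absent
    (complete-case analysis — absence is an outcome here, never an
    error, and nothing is ever imputed).  PTH is deliberately not
    inspected: a missing PTH must not exclude a patient.
    """
    if panel.age < ADULT_AGE:
        return EligibilityOutcome(EligibilityStatus.EXCLUDED, ExclusionReason.AGE_LT_18)
    if panel.hemoglobin is not None and panel.hemoglobin >= ANEMIA_HB_CUTOFF:
        return EligibilityOutcome(EligibilityStatus.EXCLUDED, ExclusionReason.HB_GE_12)
    if any(not panel.has(a) for a in KEY_ANALYTES):
        return EligibilityOutcome(
            EligibilityStatus.EXCLUDED, ExclusionReason.INCOMPLETE_RECORD
        )
    return EligibilityOutcome(EligibilityStatus.ELIGIBLE, ExclusionReason.NONE)


def recommendation_text(label: Label, ruleset: RuleSet | None = None) -> str:
    """The fixed clinical recommendation attached to a group label.

    Raises :class:`NoRecommendation` for UNCLASSIFIED — an unclassified
    patient is surfaced for review, not given automated advice.
    """
    label = Label(label)
    if label is Label.UNCLASSIFIED:
        raise NoRecommendation("no recommendation exists for UNCLASSIFIED")
    if ruleset is None:
        ruleset = build_guideline_ruleset()
    rules = ruleset.by_label(label)
    if not rules or not rules[0].recommendation:
        raise NoRecommendation(f"ruleset carries no recommendation for {label.value}")
    return rules[0].recommendation
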