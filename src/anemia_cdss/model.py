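"""Domain types and the generic rule-evaluation engine.

The clinical knowledge is expressed as flat, prioritized conjunctions of
threshold predicates over a single patient's laboratory panel.  Each rule
is a logical AND of crisp inequalities (no epsilon, no fuzziness); the
engine evaluates rules tier by tier, assigns exactly one group label per
patient, and attaches combined alerts when a lower-priority rule also
fires.  Thresholds live in configuration (see :mod:`anemia_cdss.knowledge`),
not in code, so boundary semantics stay auditable.
"""

from __future__ import annotations

import datetime
import enum
import math
from dataclasses import dataclass

import yaml

from .errors import MissingAnalyte, RulesetConflict, ValidationError

__all__ = [
    "Sex",
    "Analyte",
    "Comparator",
    "Label",
    "AnalytePanel",
    "Predicate",
    "Rule",
    "RuleSet",
    "Alert",
    "ClassificationResult",
    "Interval",
    "Overlap",
    "OverlapReport",
    "evaluate_predicate",
    "evaluate_rule",
    "classify",
    "validate_ruleset",
]


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"

    @classmethod
    def parse(cls, value: "str | Sex") -> "Sex":
        if isinstance(value, Sex):
            return value
        v = str(value).strip().lower()
        if v in ("f", "female", "femenino", "femenina", "mujer"):
            return cls.FEMALE
        if v in ("m", "male", "masculino", "hombre"):
            return cls.MALE
        raise ValidationError(f"unrecognized sex value {value!r}")


class Analyte(str, enum.Enum):
    """Variables a predicate may reference, in fixed clinical units.

    age: integer years; hemoglobin: g/dl; ferritin: ng/ml;
    tsat: transferrin saturation, percent; pth: parathyroid hormone, pg/ml.
    """

    AGE = "age"
    HEMOGLOBIN = "hemoglobin"
    FERRITIN = "ferritin"
    TSAT = "tsat"
    PTH = "pth"


class Comparator(str, enum.Enum):
    LT = "lt"
    LE = "le"
    GE = "ge"
    GT = "gt"


class Label(str, enum.Enum):
    ABSOLUTE_IRON_DEFICIT = "ABSOLUTE_IRON_DEFICIT"
    FUNCTIONAL_IRON_DEFICIT = "FUNCTIONAL_IRON_DEFICIT"
    IV_IRON_TRIAL_CANDIDATE = "IV_IRON_TRIAL_CANDIDATE"
    SEVERE_SHPT_SUSPECT = "SEVERE_SHPT_SUSPECT"
    UNCLASSIFIED = "UNCLASSIFIED"


#: the four labels a rule may carry (UNCLASSIFIED is never a rule label)
CLINICAL_LABELS = (
    Label.ABSOLUTE_IRON_DEFICIT,
    Label.FUNCTIONAL_IRON_DEFICIT,
    Label.IV_IRON_TRIAL_CANDIDATE,
    Label.SEVERE_SHPT_SUSPECT,
)


@dataclass
class AnalytePanel:
    """One patient's first laboratory result set with demographics.

    This is the unit of analysis: one record per patient, the earliest
    specimen in the study window.  Lab values are optional (``None`` =
    not measured); whether absence is acceptable is decided downstream
    by the eligibility filter, never here.

    Units are fixed: hemoglobin g/dl, ferritin ng/ml, tsat percent,
    pth pg/ml.  No unit conversion is attempted; a transferrin
    saturation outside [0, 100] is a validation error, not a clamp.
    """

    patient_id: str
    specimen_date: datetime.date
    age: int
    sex: Sex
    hemoglobin: float | None = None
    ferritin: float | None = None
    tsat: float | None = None
    pth: float | None = None

    def __post_init__(self) -> None:
        if not str(self.patient_id):
            raise ValidationError("patient_id must be non-empty")
        self.patient_id = str(self.patient_id)
        if isinstance(self.specimen_date, datetime.datetime):
            self.specimen_date = self.specimen_date.date()
        if not isinstance(self.specimen_date, datetime.date):
            raise ValidationError(
                f"specimen_date must be a date, got {self.specimen_date!r}"
            )
        # age is completed years ("anos cumplidos"): fractional ages floored
        if self.age is None or (isinstance(self.age, float) and math.isnan(self.age)):
            raise ValidationError("age is required")
        self.age = int(math.floor(float(self.age)))
        if self.age < 0:
            raise ValidationError(f"age must be >= 0, got {self.age}")
        self.sex = Sex.parse(self.sex)
        for name in ("hemoglobin", "ferritin", "pth"):
            v = getattr(self, name)
            if v is not None:
                v = float(v)
                if not math.isfinite(v) or v < 0:
                    raise ValidationError(f"{name} must be finite and >= 0, got {v}")
                setattr(self, name, v)
        if self.tsat is not None:
            t = float(self.tsat)
            if not math.isfinite(t) or not (0.0 <= t <= 100.0):
                raise ValidationError(f"tsat must lie in [0, 100], got {t}")
            self.tsat = t

    def value(self, analyte: Analyte) -> float:
        """Return the analyte's value, raising :class:`MissingAnalyte` if absent."""
        v = getattr(self, Analyte(analyte).value)
        if v is None:
            raise MissingAnalyte(Analyte(analyte).value)
        return float(v)

    def has(self, analyte: Analyte) -> bool:
        return getattr(self, Analyte(analyte).value) is not None


_COMPARE = {
    Comparator.LT: lambda v, t: v < t,
    Comparator.LE: lambda v, t: v <= t,
    Comparator.GE: lambda v, t: v >= t,
    Comparator.GT: lambda v, t: v > t,
}


@dataclass(frozen=True)
class Predicate:
    """A single threshold comparison, e.g. ``ferritin < 200``."""

    analyte: Analyte
    comparator: Comparator
    threshold: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "analyte", Analyte(self.analyte))
        object.__setattr__(self, "comparator", Comparator(self.comparator))
        t = float(self.threshold)
        if not math.isfinite(t):
            raise ValidationError(f"threshold must be finite, got {t!r}")
        object.__setattr__(self, "threshold", t)

    def __str__(self) -> str:  # e.g. "ferritin lt 200"
        return f"{self.analyte.value} {self.comparator.value} {self.threshold:g}"


@dataclass(frozen=True)
class Rule:
    """A conjunction of predicates carrying a group label and a recommendation.

    ``tier`` orders evaluation: lower tiers are classification rules,
    higher tiers are fallback/alert rules (lower = evaluated first).
    """

    rule_id: str
    label: Label
    predicates: tuple[Predicate, ...]
    tier: int = 0
    recommendation: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", Label(self.label))
        preds = tuple(self.predicates)
        if not preds:
            raise ValidationError(f"rule {self.rule_id!r} has no predicates")
        object.__setattr__(self, "predicates", preds)
        object.__setattr__(self, "tier", int(self.tier))

    @property
    def analytes(self) -> frozenset[Analyte]:
        return frozenset(p.analyte for p in self.predicates)


@dataclass
class RuleSet:
    """An ordered, uniquely-identified collection of rules."""

    rules: list[Rule]
    name: str = "ruleset"
    version: str = "0"

    def __post_init__(self) -> None:
        ids = [r.rule_id for r in self.rules]
        if len(ids) != len(set(ids)):
            raise ValidationError("rule_id values must be unique within a RuleSet")

    def __iter__(self):
        return iter(self.rules)

    def __len__(self) -> int:
        return len(self.rules)

    def tiers(self) -> list[int]:
        return sorted({r.tier for r in self.rules})

    def tier_rules(self, tier: int) -> list[Rule]:
        return [r for r in self.rules if r.tier == tier]

    def by_label(self, label: Label) -> list[Rule]:
        return [r for r in self.rules if r.label == Label(label)]

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "version": self.version,
            "rules": [
                {
                    "rule_id": r.rule_id,
                    "label": r.label.value,
                    "tier": r.tier,
                    "recommendation": r.recommendation,
                    "predicates": [
                        {
                            "analyte": p.analyte.value,
                            "comparator": p.comparator.value,
                            "threshold": p.threshold,
                        }
                        for p in r.predicates
                    ],
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RuleSet":
        try:
            rules = [
                Rule(
                    rule_id=r["rule_id"],
                    label=Label(r["label"]),
                    tier=int(r.get("tier", 0)),
                    recommendation=r.get("recommendation", ""),
                    predicates=tuple(
                        Predicate(p["analyte"], p["comparator"], p["threshold"])
                        for p in r["predicates"]
                    ),
                )
                for r in data["rules"]
            ]
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"malformed ruleset document: {exc}") from exc
        return cls(rules=rules, name=data.get("name", "ruleset"),
                   version=str(data.get("version", "0")))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RuleSet":
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class Alert:
    alert_code: str
    message: str


@dataclass
class ClassificationResult:
    """Outcome of classifying one panel: exactly one label plus alerts."""

    patient_id: str
    label: Label
    fired_rule_ids: frozenset[str] = frozenset()
    alerts: tuple[Alert, ...] = ()

    def __post_init__(self) -> None:
        self.label = Label(self.label)
        self.fired_rule_ids = frozenset(self.fired_rule_ids)
        self.alerts = tuple(self.alerts)
        if self.label is not Label.UNCLASSIFIED and not self.fired_rule_ids:
            raise ValidationError(
                "a classified result must carry the rule ids that fired"
            )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def evaluate_predicate(panel: AnalytePanel, predicate: Predicate) -> bool:
    """Truth of one threshold comparison on one panel.

    Strict/non-strict exactly as the comparator states; raises
    :class:`MissingAnalyte` (never a default boolean) when the analyte
    is absent.
    """
    value = panel.value(predicate.analyte)
    return _COMPARE[predicate.comparator](value, predicate.threshold)


def evaluate_rule(panel: AnalytePanel, rule: Rule) -> bool:
    """Logical AND of all of the rule's predicates on the panel.

    Every predicate is evaluated (no observable short-circuit); a
    missing analyte anywhere in the conjunction raises
    :class:`MissingAnalyte`.
    """
    results = [evaluate_predicate(panel, p) for p in rule.predicates]
    return all(results)


def _rule_fires(panel: AnalytePanel, rule: Rule) -> bool:
    """Like evaluate_rule, but a rule needing an absent PTH simply does not fire.

    PTH is the only optional analyte at classification time: patients
    without a PTH measurement remain classifiable by the iron rules and
    can never trigger the PTH rule or alert.  Absence of any other
    analyte still raises.
    """
    if Analyte.PTH in rule.analytes and not panel.has(Analyte.PTH):
        return False
    return evaluate_rule(panel, rule)


SHPT_COMBINED = "SHPT_COMBINED"


def classify(panel: AnalytePanel, ruleset: RuleSet) -> ClassificationResult:
    """Assign exactly one group label (or UNCLASSIFIED) plus alerts.

    Tiers are evaluated in ascending order.  The first tier in which a
    rule fires provides the label; two rules firing in that same tier is
    a :class:`RulesetConflict` (impossible for a ruleset whose same-tier
    regions are disjoint, see :func:`validate_ruleset`).  Rules in later
    tiers that also fire do not change the label: they attach a combined
    alert — e.g. an iron-deficit patient whose PTH also exceeds the
    severe-hyperparathyroidism threshold keeps the iron label and gains
    an ``SHPT_COMBINED`` alert.
    """
    label: Label | None = None
    fired: set[str] = set()
    alerts: list[Alert] = []
    for tier in ruleset.tiers():
        tier_fired = [r for r in ruleset.tier_rules(tier) if _rule_fires(panel, r)]
        if not tier_fired:
            continue
        if label is None:
            if len(tier_fired) > 1:
                ids = ", ".join(r.rule_id for r in tier_fired)
                raise RulesetConflict(
                    f"rules [{ids}] in tier {tier} all fired for patient "
                    f"{panel.patient_id!r}"
                )
            rule = tier_fired[0]
            label = rule.label
            fired.add(rule.rule_id)
        else:
            for rule in tier_fired:
                fired.add(rule.rule_id)
                code = (
                    SHPT_COMBINED
                    if rule.label is Label.SEVERE_SHPT_SUSPECT
                    else f"{rule.label.value}_COMBINED"
                )
                alerts.append(Alert(code, rule.recommendation))
    return ClassificationResult(
        patient_id=panel.patient_id,
        label=label if label is not None else Label.UNCLASSIFIED,
        fired_rule_ids=frozenset(fired),
        alerts=tuple(alerts),
    )


# ---------------------------------------------------------------------------
# ruleset validation: pairwise intersection of conjunctive regions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Interval:
    """A (possibly half-open, possibly unbounded) interval on one analyte axis."""

    lower: float = -math.inf
    upper: float = math.inf
    lower_closed: bool = False
    upper_closed: bool = False

    def is_empty(self) -> bool:
        if self.lower > self.upper:
            return True
        if self.lower == self.upper:
            return not (self.lower_closed and self.upper_closed)
        return False

    def intersect(self, other: "Interval") -> "Interval":
        if self.lower > other.lower:
            lo, lo_c = self.lower, self.lower_closed
        elif self.lower < other.lower:
            lo, lo_c = other.lower, other.lower_closed
        else:
            lo, lo_c = self.lower, self.lower_closed and other.lower_closed
        if self.upper < other.upper:
            hi, hi_c = self.upper, self.upper_closed
        elif self.upper > other.upper:
            hi, hi_c = other.upper, other.upper_closed
        else:
            hi, hi_c = self.upper, self.upper_closed and other.upper_closed
        return Interval(lo, hi, lo_c, hi_c)

    def __str__(self) -> str:
        lo = "[" if self.lower_closed else "("
        hi = "]" if self.upper_closed else ")"
        return f"{lo}{self.lower:g}, {self.upper:g}{hi}"


def rule_region(rule: Rule) -> dict[Analyte, Interval]:
    """The axis-aligned hyper-rectangle on which the conjunction is true."""
    region: dict[Analyte, Interval] = {}
    for p in rule.predicates:
        if p.comparator is Comparator.LT:
            iv = Interval(upper=p.threshold, upper_closed=False)
        elif p.comparator is Comparator.LE:
            iv = Interval(upper=p.threshold, upper_closed=True)
        elif p.comparator is Comparator.GE:
            iv = Interval(lower=p.threshold, lower_closed=True)
        else:  # GT
            iv = Interval(lower=p.threshold, lower_closed=False)
        region[p.analyte] = region[p.analyte].intersect(iv) if p.analyte in region else iv
    return region


@dataclass(frozen=True)
class Overlap:
    rule_a: str
    rule_b: str
    tier: int
    region: dict  # Analyte -> Interval of the shared hyper-rectangle


@dataclass
class OverlapReport:
    """Pairwise same-tier overlap analysis of a ruleset."""

    pairs_checked: int
    overlaps: list[Overlap]

    @property
    def is_disjoint(self) -> bool:
        return not self.overlaps


def validate_ruleset(ruleset: RuleSet) -> OverlapReport:
    """Report every pair of same-tier rules whose conjunctive regions intersect.

    Two conjunctions of interval constraints overlap iff, on every axis
    constrained by either rule, their intervals intersect (an axis one
    rule leaves unconstrained never separates them).  Returns the
    intersecting hyper-rectangle for each overlapping pair.  A ruleset
    whose group counts must partition a cohort should come back with
    zero same-tier overlaps.
    """
    if not len(ruleset):
        raise ValidationError("ruleset is empty")
    for rule in ruleset:
        for p in rule.predicates:
            if not isinstance(p, Predicate):
                raise ValidationError(f"rule {rule.rule_id!r} has a malformed predicate")
    overlaps: list[Overlap] = []
    pairs = 0
    for tier in ruleset.tiers():
        rules = ruleset.tier_rules(tier)
        regions = {r.rule_id: rule_region(r) for r in rules}
        for i, a in enumerate(rules):
            for b in rules[i + 1:]:
                pairs += 1
                ra, rb = regions[a.rule_id], regions[b.rule_id]
                shared: dict[Analyte, Interval] = {}
                empty = False
                for analyte in sorted(set(ra) | set(rb), key=lambda x: x.value):
                    iv = ra.get(analyte, Interval()).intersect(
                        rb.get(analyte, Interval())
                    )
                    if iv.is_empty():
                        empty = True
                        break
                    shared[analyte] = iv
                if not empty:
                    overlaps.append(
                        Overlap(rule_a=a.rule_id, rule_b=b.rule_id, tier=tier,
                                region=shared)
                    )
    return OverlapReport(pairs_checked=pairs, overlaps=overlaps)
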