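"""Synthetic hemodialysis cohorts with the study population's structure.

No patient-level data accompany the published cohort, so downstream
stages are exercised on simulated cohorts that reproduce its printed
structure: four clinical groups with the published sizes (346 functional
iron deficit, 156 absolute, 145 IV-iron trial candidates, 236 suspected
severe secondary hyperparathyroidism; 883 in total), the published age
means/SDs and female proportions, and lab values drawn from truncated
normal distributions centered on the published group means with
truncation bounds strictly inside each group's rule region — so every
generated record provably classifies back to its generating label.

Distributional family (truncated normal) and the lab-analyte SDs are
generator assumptions, not published quantities; see docs/methods.md.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import SpecError
from .knowledge import eligibility_filter
from .model import Analyte, AnalytePanel, Label, RuleSet, Sex, classify

__all__ = [
    "TruncNorm",
    "GroupSpec",
    "LabeledRecord",
    "default_group_specs",
    "generate_cohort",
    "inject_ineligible",
]

#: study year for simulated specimen dates
STUDY_YEAR = 2023


@dataclass(frozen=True)
class TruncNorm:
    """Truncated normal parameters (mean/sd of the parent, hard bounds)."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower < self.upper):
            raise SpecError(f"truncation bounds must satisfy lower < upper: {self}")
        if self.sd <= 0:
            raise SpecError(f"sd must be positive: {self}")

    def _ab(self) -> tuple[float, float]:
        return ((self.lower - self.mean) / self.sd,
                (self.upper - self.mean) / self.sd)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a, b = self._ab()
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                   size=n, random_state=rng)

    @property
    def expected_mean(self) -> float:
        """Mean of the truncated distribution (differs from the parent mean)."""
        a, b = self._ab()
        return float(stats.truncnorm.mean(a, b, loc=self.mean, scale=self.sd))

    @property
    def expected_sd(self) -> float:
        a, b = self._ab()
        return float(stats.truncnorm.std(a, b, loc=self.mean, scale=self.sd))


@dataclass(frozen=True)
class GroupSpec:
    """Generative description of one clinical group.

    ``analyte_dists`` maps hemoglobin/ferritin/tsat to truncated normals
    whose bounds lie strictly inside the group's rule region.
    ``pth_dist`` is optional; ``n_with_pth`` says how many of the group's
    records receive a PTH value from it (the rest leave PTH absent,
    mirroring a source table where iron groups mostly lack PTH).
    """

    label: Label
    n: int
    age_mean: float
    age_sd: float
    female_prop: float
    analyte_dists: dict[Analyte, TruncNorm]
    pth_dist: TruncNorm | None = None
    n_with_pth: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise SpecError("n must be >= 0")
        if not (0.0 <= self.female_prop <= 1.0):
            raise SpecError("female_prop must lie in [0, 1]")
        if self.n_with_pth < 0 or self.n_with_pth > self.n:
            raise SpecError("n_with_pth must lie in [0, n]")
        if self.n_with_pth > 0 and self.pth_dist is None:
            raise SpecError("n_with_pth > 0 requires a pth_dist")


@dataclass(frozen=True)
class LabeledRecord:
    """A generated panel together with its ground-truth group label.

    ``true_label`` is ``None`` for injected ineligible padding records;
    ``exclusion_reason`` then names the eligibility criterion they violate.
    """

    panel: AnalytePanel
    true_label: Label | None
    exclusion_reason: str | None = None


def default_group_specs() -> list[GroupSpec]:
    """The published cohort structure as generator defaults.

    Group sizes, age means/SDs, female proportions and lab means are the
    published per-group values; lab SDs and truncation margins are
    generator assumptions.  Within the functional group, exactly 33
    records carry PTH above 800 pg/ml (the published co-occurrence,
    9.5 % of 346).  The severe-SHPT group's iron panel is drawn with
    ferritin above 500 ng/ml, outside all three iron-rule regions, so
    the four groups stay mutually exclusive.
    """
    hb_sd, ferr_sd, tsat_sd, pth_sd = 1.0, 80.0, 3.0, 400.0
    high_pth = TruncNorm(mean=1378.5, sd=pth_sd, lower=810.0, upper=3500.0)
    return [
        GroupSpec(
            label=Label.FUNCTIONAL_IRON_DEFICIT, n=346,
            age_mean=58.5, age_sd=16.4, female_prop=0.436,
            analyte_dists={
                Analyte.HEMOGLOBIN: TruncNorm(10.4, hb_sd, 7.0, 11.9),
                Analyte.FERRITIN: TruncNorm(369.2, ferr_sd, 200.5, 499.5),
                Analyte.TSAT: TruncNorm(14.1, tsat_sd, 1.0, 19.9),
            },
            pth_dist=high_pth, n_with_pth=33,
        ),
        GroupSpec(
            label=Label.ABSOLUTE_IRON_DEFICIT, n=156,
            age_mean=57.5, age_sd=15.3, female_prop=0.391,
            analyte_dists={
                Analyte.HEMOGLOBIN: TruncNorm(10.2, hb_sd, 7.0, 11.9),
                Analyte.FERRITIN: TruncNorm(118.7, ferr_sd, 5.0, 199.5),
                Analyte.TSAT: TruncNorm(11.3, tsat_sd, 1.0, 19.9),
            },
        ),
        GroupSpec(
            label=Label.IV_IRON_TRIAL_CANDIDATE, n=145,
            age_mean=59.2, age_sd=16.8, female_prop=0.345,
            analyte_dists={
                Analyte.HEMOGLOBIN: TruncNorm(10.7, hb_sd, 7.0, 11.9),
                Analyte.FERRITIN: TruncNorm(372.5, ferr_sd, 200.5, 499.5),
                Analyte.TSAT: TruncNorm(23.6, tsat_sd, 20.1, 29.9),
            },
        ),
        GroupSpec(
            label=Label.SEVERE_SHPT_SUSPECT, n=236,
            age_mean=47.5, age_sd=16.0, female_prop=0.500,
            analyte_dists={
                Analyte.HEMOGLOBIN: TruncNorm(10.5, hb_sd, 7.0, 11.9),
                # ferritin > 500 keeps every iron rule false regardless of TSAT
                Analyte.FERRITIN: TruncNorm(650.0, ferr_sd, 505.0, 1000.0),
                Analyte.TSAT: TruncNorm(15.0, tsat_sd, 1.0, 19.9),
            },
            pth_dist=high_pth, n_with_pth=236,
        ),
    ]


def _corner_panels(spec: GroupSpec) -> list[AnalytePanel]:
    """Panels at every corner of the spec's truncation hyper-rectangle."""
    analytes = sorted(spec.analyte_dists, key=lambda a: a.value)
    panels = []
    for mask in range(2 ** len(analytes)):
        values = {
            a.value: (spec.analyte_dists[a].lower if mask >> i & 1
                      else spec.analyte_dists[a].upper)
            for i, a in enumerate(analytes)
        }
        for pth in ([spec.pth_dist.lower, spec.pth_dist.upper]
                    if spec.n_with_pth else [None]):
            panels.append(AnalytePanel(
                patient_id="corner", specimen_date=datetime.date(STUDY_YEAR, 1, 1),
                age=18, sex=Sex.FEMALE, pth=pth, **values,
            ))
    return panels


def _check_spec_region(spec: GroupSpec, ruleset: RuleSet) -> None:
    """Every truncation corner must classify to the spec's label."""
    for panel in _corner_panels(spec):
        result = classify(panel, ruleset)
        if result.label is not spec.label:
            raise SpecError(
                f"truncation bounds of spec {spec.label.value} leave its rule "
                f"region: corner panel classified as {result.label.value}"
            )


def generate_cohort(
    specs: list[GroupSpec],
    seed: int,
    ruleset: RuleSet | None = None,
) -> list[LabeledRecord]:
    """Draw one deterministic cohort from the group specifications.

    Ages come from a truncated normal bounded below at 18 years and are
    floored to completed years; sex is Bernoulli(female_prop); labs come
    from their truncated normals; specimen dates are uniform over the
    study year.  When a ruleset is supplied (default: the shipped
    guideline ruleset) the spec bounds are checked against it first and
    a :class:`SpecError` is raised if any truncation corner escapes the
    spec's rule region.  Output order is deterministic given the seed.
    """
    if ruleset is None:
        from .knowledge import build_guideline_ruleset
        ruleset = build_guideline_ruleset()
    for spec in specs:
        if spec.n > 0:
            _check_spec_region(spec, ruleset)
    rng = np.random.default_rng(seed)
    records: list[LabeledRecord] = []
    counter = 0
    for spec in specs:
        n = spec.n
        if n == 0:
            continue
        ages = np.floor(TruncNorm(spec.age_mean, spec.age_sd, 18.0, 100.0)
                        .sample(n, rng)).astype(int)
        female = rng.random(n) < spec.female_prop
        day_offsets = rng.integers(0, 365, size=n)
        labs = {
            a: spec.analyte_dists[a].sample(n, rng)
            for a in sorted(spec.analyte_dists, key=lambda x: x.value)
        }
        pth = np.full(n, np.nan)
        if spec.n_with_pth:
            chosen = rng.choice(n, size=spec.n_with_pth, replace=False)
            pth[chosen] = spec.pth_dist.sample(spec.n_with_pth, rng)
        for i in range(n):
            counter += 1
            panel = AnalytePanel(
                patient_id=f"S{counter:05d}",
                specimen_date=(datetime.date(STUDY_YEAR, 1, 1)
                               + datetime.timedelta(days=int(day_offsets[i]))),
                age=int(ages[i]),
                sex=Sex.FEMALE if female[i] else Sex.MALE,
                hemoglobin=float(labs[Analyte.HEMOGLOBIN][i]),
                ferritin=float(labs[Analyte.FERRITIN][i]),
                tsat=float(labs[Analyte.TSAT][i]),
                pth=None if np.isnan(pth[i]) else float(pth[i]),
            )
            records.append(LabeledRecord(panel=panel, true_label=spec.label))
    return records


def inject_ineligible(
    records: list[LabeledRecord],
    n_minor: int,
    n_high_hb: int,
    n_incomplete: int,
    seed: int,
) -> list[LabeledRecord]:
    """Append records violating each eligibility criterion, then shuffle.

    Injected records carry ``true_label=None`` and the ground-truth
    exclusion reason (age_lt_18 / hb_ge_12 / incomplete_record), so an
    ingest-filter run over the augmented cohort can be audited exactly.
    The shuffle is deterministic given the seed.
    """
    if min(n_minor, n_high_hb, n_incomplete) < 0:
        raise SpecError("injection counts must be >= 0")
    rng = np.random.default_rng(seed)
    extra: list[LabeledRecord] = []
    counter = 0

    def base_panel(pid: str, **overrides) -> AnalytePanel:
        kwargs = dict(
            patient_id=pid,
            specimen_date=(datetime.date(STUDY_YEAR, 1, 1)
                           + datetime.timedelta(days=int(rng.integers(0, 365)))),
            age=int(rng.integers(25, 85)),
            sex=Sex.FEMALE if rng.random() < 0.5 else Sex.MALE,
            hemoglobin=float(rng.uniform(8.0, 11.5)),
            ferritin=float(rng.uniform(50.0, 600.0)),
            tsat=float(rng.uniform(5.0, 35.0)),
        )
        kwargs.update(overrides)
        return AnalytePanel(**kwargs)

    for _ in range(n_minor):
        counter += 1
        extra.append(LabeledRecord(
            panel=base_panel(f"X{counter:04d}", age=int(rng.integers(1, 18))),
            true_label=None, exclusion_reason="age_lt_18",
        ))
    for _ in range(n_high_hb):
        counter += 1
        extra.append(LabeledRecord(
            panel=base_panel(f"X{counter:04d}",
                             hemoglobin=float(rng.uniform(12.0, 15.5))),
            true_label=None, exclusion_reason="hb_ge_12",
        ))
    missing_cycle = (Analyte.HEMOGLOBIN, Analyte.FERRITIN, Analyte.TSAT)
    for i in range(n_incomplete):
        counter += 1
        dropped = missing_cycle[i % 3]
        extra.append(LabeledRecord(
            panel=base_panel(f"X{counter:04d}", **{dropped.value: None}),
            true_label=None, exclusion_reason="incomplete_record",
        ))
    # guard: every injected record must actually fail the filter as intended
    for rec in extra:
        outcome = eligibility_filter(rec.panel)
        assert not outcome.eligible and outcome.reason.value == rec.exclusion_reason

    augmented = list(records) + extra
    order = rng.permutation(len(augmented))
    return [augmented[i] for i in order]
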