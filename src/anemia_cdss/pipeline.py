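"""End-to-end cohort stage: classify, summarize, export reports.

Turns an ingested (eligible, complete) cohort into per-patient
classifications, per-group descriptive statistics mirroring the study's
Table-1 layout, the functional-deficit/high-PTH co-occurrence
statistic, and boxplot-ready long-format exports.  Only descriptive
statistics are computed — no inferential analysis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ReportError, ValidationError
from .model import (
    AnalytePanel,
    ClassificationResult,
    Label,
    RuleSet,
    classify,
)

__all__ = [
    "AnalyteStats",
    "GroupRow",
    "Cooccurrence",
    "CohortSummary",
    "classify_cohort",
    "summarize_cohort",
    "cooccurrence_count",
    "export_reports",
]

#: PTH threshold for the co-occurrence statistic, pg/ml
DEFAULT_PTH_THRESHOLD = 800.0

#: canonical report order for group rows
LABEL_ORDER = (
    Label.FUNCTIONAL_IRON_DEFICIT,
    Label.ABSOLUTE_IRON_DEFICIT,
    Label.IV_IRON_TRIAL_CANDIDATE,
    Label.SEVERE_SHPT_SUSPECT,
    Label.UNCLASSIFIED,
)

_ANALYTE_COLS = ("hemoglobin", "ferritin", "tsat", "pth")


@dataclass(frozen=True)
class AnalyteStats:
    """Descriptive statistics for one analyte within one group.

    ``sd`` is the sample standard deviation (n−1 denominator) and is
    ``None`` for n = 1; quantiles use linear interpolation between
    order statistics; ``iqr`` is Q3 − Q1.
    """

    n: int
    mean: float
    sd: float | None
    median: float
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass
class GroupRow:
    label: Label
    n: int
    pct_of_cohort: float | None
    age_mean: float | None = None
    age_sd: float | None = None
    female_pct: float | None = None
    analytes: dict[str, AnalyteStats] = field(default_factory=dict)


@dataclass(frozen=True)
class Cooccurrence:
    """Functional-deficit patients whose PTH also exceeds the threshold."""

    n: int
    pct_of_functional: float | None


@dataclass
class CohortSummary:
    groups: list[GroupRow]
    n_total: int
    age_mean: float | None
    age_sd: float | None
    female_pct: float | None
    cooccurrence: Cooccurrence

    def group(self, label: Label) -> GroupRow:
        for row in self.groups:
            if row.label is Label(label):
                return row
        raise KeyError(label)


def classify_cohort(
    panels: Sequence[AnalytePanel], ruleset: RuleSet
) -> list[ClassificationResult]:
    """One classification per panel, in stable input order."""
    return [classify(panel, ruleset) for panel in panels]


def _series_stats(values: pd.Series) -> AnalyteStats | None:
    values = values.dropna()
    n = int(values.size)
    if n == 0:
        return None
    return AnalyteStats(
        n=n,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if n > 1 else None,
        median=float(values.median()),
        q1=float(values.quantile(0.25)),  # linear interpolation
        q3=float(values.quantile(0.75)),
    )


def _to_frame(
    panels: Sequence[AnalytePanel], results: Sequence[ClassificationResult]
) -> pd.DataFrame:
    if len(panels) != len(results):
        raise ValidationError("panels and results must align one-to-one")
    for p, r in zip(panels, results):
        if p.patient_id != r.patient_id:
            raise ValidationError(
                f"panel/result mismatch at patient {p.patient_id!r} vs {r.patient_id!r}"
            )
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in panels],
            "label": [r.label.value for r in results],
            "age": [p.age for p in panels],
            "female": [p.sex.value == "female" for p in panels],
            "hemoglobin": [p.hemoglobin for p in panels],
            "ferritin": [p.ferritin for p in panels],
            "tsat": [p.tsat for p in panels],
            "pth": [p.pth for p in panels],
        }
    )


def summarize_cohort(
    panels: Sequence[AnalytePanel],
    results: Sequence[ClassificationResult],
    pth_threshold: float = DEFAULT_PTH_THRESHOLD,
) -> CohortSummary:
    """Per-group and overall descriptive statistics.

    Every label (including UNCLASSIFIED) gets a row, so the group sizes
    always partition the cohort; a group with n = 0 keeps its row with
    statistics marked absent.  Percentages and means are kept at full
    precision here — rounding to the report's one-decimal display
    happens only at export.
    """
    df = _to_frame(panels, results)
    n_total = len(df)
    groups: list[GroupRow] = []
    for label in LABEL_ORDER:
        sub = df[df["label"] == label.value]
        n = len(sub)
        row = GroupRow(
            label=label,
            n=n,
            pct_of_cohort=(100.0 * n / n_total) if n_total else None,
        )
        if n > 0:
            row.age_mean = float(sub["age"].mean())
            row.age_sd = float(sub["age"].std(ddof=1)) if n > 1 else None
            row.female_pct = 100.0 * float(sub["female"].mean())
            for col in _ANALYTE_COLS:
                st = _series_stats(sub[col])
                if st is not None:
                    row.analytes[col] = st
        groups.append(row)
    cooc = cooccurrence_count(panels, results, pth_threshold)
    return CohortSummary(
        groups=groups,
        n_total=n_total,
        age_mean=float(df["age"].mean()) if n_total else None,
        age_sd=float(df["age"].std(ddof=1)) if n_total > 1 else None,
        female_pct=100.0 * float(df["female"].mean()) if n_total else None,
        cooccurrence=cooc,
    )


def cooccurrence_count(
    panels: Sequence[AnalytePanel],
    results: Sequence[ClassificationResult],
    pth_threshold: float = DEFAULT_PTH_THRESHOLD,
) -> Cooccurrence:
    """Count functional-iron-deficit patients with PTH above the threshold.

    The percentage is relative to the functional group's size and is
    undefined (``None``) when that group is empty.
    """
    if pth_threshold <= 0:
        raise ValidationError("pth_threshold must be positive")
    n_functional = 0
    n_high = 0
    for panel, result in zip(panels, results):
        if result.label is Label.FUNCTIONAL_IRON_DEFICIT:
            n_functional += 1
            if panel.pth is not None and panel.pth > pth_threshold:
                n_high += 1
    if n_functional == 0:
        return Cooccurrence(n=0, pct_of_functional=None)
    return Cooccurrence(n=n_high, pct_of_functional=100.0 * n_high / n_functional)


# ---------------------------------------------------------------------------
# report export
# ---------------------------------------------------------------------------

_GROUP_DISPLAY = {
    Label.FUNCTIONAL_IRON_DEFICIT: "Functional iron deficit",
    Label.ABSOLUTE_IRON_DEFICIT: "Absolute iron deficit",
    Label.IV_IRON_TRIAL_CANDIDATE: "IV iron therapeutic trial candidates",
    Label.SEVERE_SHPT_SUSPECT: "Suspected severe secondary hyperparathyroidism",
    Label.UNCLASSIFIED: "Unclassified",
}


def _fmt(value: float | None, decimals: int = 1) -> str:
    # locale-stable: always '.' decimal point, '-' for absent cells
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "-"
    return f"{value:.{decimals}f}"


def export_reports(
    summary: CohortSummary,
    panels: Sequence[AnalytePanel],
    results: Sequence[ClassificationResult],
    destination: "str | Path",
    manifest_extra: dict | None = None,
) -> dict[str, Path]:
    """Write the Table-1-style report, the boxplot-ready long table, and a manifest.

    Emits, under ``destination``: ``table1.csv`` (one row per group with
    n, % of cohort, age mean (SD), % female, and analyte means, absent
    cells as "-"; display rounding one decimal), ``long_values.csv``
    (patient_id, label, analyte, value — one row per present analyte,
    ready for boxplots), and ``manifest.json`` (counts funnel and any
    extra run metadata).  Rendering is locale-stable: the same summary
    always yields byte-identical files.
    """
    dest = Path(destination)
    try:
        dest.mkdir(parents=True, exist_ok=True)

        table1 = dest / "table1.csv"
        lines = [
            "group,n,pct_of_cohort,age_mean,age_sd,female_pct,"
            "hb_mean,ferritin_mean,tsat_mean,pth_mean"
        ]
        for row in summary.groups:
            # UNCLASSIFIED patients are never dropped, but an empty
            # UNCLASSIFIED row would add a line the source table lacks
            if row.n == 0 and row.label is Label.UNCLASSIFIED:
                continue
            cells = [
                _GROUP_DISPLAY[row.label],
                str(row.n),
                _fmt(row.pct_of_cohort),
                _fmt(row.age_mean),
                _fmt(row.age_sd),
                _fmt(row.female_pct),
            ]
            for col in _ANALYTE_COLS:
                st = row.analytes.get(col)
                cells.append(_fmt(st.mean if st else None))
            lines.append(",".join(f'"{c}"' if "," in c else c for c in cells))
        table1.write_text("\n".join(lines) + "\n", encoding="utf-8")

        long_path = dest / "long_values.csv"
        long_lines = ["patient_id,label,analyte,value"]
        for panel, result in zip(panels, results):
            for col in _ANALYTE_COLS:
                value = getattr(panel, col)
                if value is not None:
                    long_lines.append(
                        f"{panel.patient_id},{result.label.value},{col},{value!r}"
                    )
        long_path.write_text("\n".join(long_lines) + "\n", encoding="utf-8")

        manifest_path = dest / "manifest.json"
        manifest = {
            "n_total": summary.n_total,
            "groups": {row.label.value: row.n for row in summary.groups},
            "cooccurrence": {
                "n": summary.cooccurrence.n,
                "pct_of_functional": summary.cooccurrence.pct_of_functional,
            },
        }
        if manifest_extra:
            manifest.update(manifest_extra)
        manifest_path.write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    except OSError as exc:
        raise ReportError(f"failed writing reports to {dest}: {exc}") from exc
    return {"table1": table1, "long_values": long_path, "manifest": manifest_path}
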