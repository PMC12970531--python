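"""Cohort ingestion: delimited tables, HL7 v2 ORU messages, dedup, filtering.

Reads laboratory exports into :class:`~anemia_cdss.model.AnalytePanel`
records, keeps the first result set per patient, and applies the
eligibility / complete-case filter with a full audit trail.  Nothing in
this module ever fabricates or imputes an analyte value; a record that
cannot be parsed or validated becomes an issue in the report, never a
silent default.
"""

from __future__ import annotations

import csv
import datetime
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from .errors import FormatError, MessageError, ValidationError
from .knowledge import EligibilityOutcome, eligibility_filter
from .model import Analyte, AnalytePanel, Sex

__all__ = [
    "TableDialect",
    "SPANISH_DIALECT",
    "IngestReport",
    "read_cohort_table",
    "write_cohort_table",
    "first_record_per_patient",
    "apply_filters",
    "ingest_cohort",
    "parse_hl7_oru",
    "DEFAULT_CODE_MAP",
]

#: canonical column order for cohort tables
COLUMNS = (
    "patient_id", "specimen_date", "age", "sex",
    "hemoglobin", "ferritin", "tsat", "pth",
)
MANDATORY_COLUMNS = ("patient_id", "specimen_date", "age")
OPTIONAL_VALUE_TOKENS = {"", "-", "na", "nan", "null", "none"}


@dataclass(frozen=True)
class TableDialect:
    """Separator and decimal-mark configuration for delimited cohort tables.

    Spanish-locale LIS exports use semicolon separation with a decimal
    comma ("369,2"); the canonical dialect is comma/point.
    """

    separator: str = ","
    decimal_mark: str = "."

    def __post_init__(self) -> None:
        if self.separator == self.decimal_mark:
            raise ValidationError("separator and decimal mark must differ")


SPANISH_DIALECT = TableDialect(separator=";", decimal_mark=",")


@dataclass
class IngestReport:
    """Audit trail of the ingestion funnel: input -> dedup -> eligible."""

    n_input: int = 0
    n_after_dedup: int = 0
    n_eligible: int = 0
    exclusions: dict[str, int] = field(default_factory=dict)
    issues: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if not (self.n_input >= self.n_after_dedup >= self.n_eligible):
            raise ValidationError("funnel counts must be non-increasing")
        if sum(self.exclusions.values()) != self.n_after_dedup - self.n_eligible:
            raise ValidationError("exclusion counts do not account for the funnel")

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_after_dedup": self.n_after_dedup,
                "n_eligible": self.n_eligible,
                "exclusions": dict(self.exclusions),
                "issues": list(self.issues),
            },
            indent=indent,
        )


def _parse_number(token: str, dialect: TableDialect) -> float | None:
    token = token.strip()
    if token.lower() in OPTIONAL_VALUE_TOKENS:
        return None
    if dialect.decimal_mark != ".":
        if "." in token:
            raise ValueError(f"unexpected '.' in {token!r} for decimal-comma dialect")
        token = token.replace(dialect.decimal_mark, ".")
    value = float(token)
    if not math.isfinite(value):
        raise ValueError(f"non-finite value {token!r}")
    return value


def read_cohort_table(
    source: "str | Path | TextIO",
    dialect: TableDialect = TableDialect(),
) -> tuple[list[AnalytePanel], list[str]]:
    """Read a delimited cohort table into panels plus per-row issues.

    The header must name at least patient_id, specimen_date and age
    (missing mandatory columns raise :class:`FormatError`); rows whose
    values fail parsing or panel validation are dropped and recorded as
    issues, never crashes.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return read_cohort_table(fh, dialect)
    reader = csv.reader(source, delimiter=dialect.separator)
    try:
        header = next(reader)
    except StopIteration:
        raise FormatError("empty input: no header row") from None
    header = [h.strip().lower() for h in header]
    missing = [c for c in MANDATORY_COLUMNS if c not in header]
    if missing:
        raise FormatError(f"missing mandatory columns: {', '.join(missing)}")
    idx = {name: header.index(name) for name in COLUMNS if name in header}

    panels: list[AnalytePanel] = []
    issues: list[str] = []
    for lineno, row in enumerate(reader, start=2):
        if not any(cell.strip() for cell in row):
            continue
        try:
            panels.append(_row_to_panel(row, idx, dialect))
        except (ValueError, ValidationError, IndexError) as exc:
            issues.append(f"line {lineno}: {exc}")
    return panels, issues


def _row_to_panel(row: Sequence[str], idx: dict[str, int],
                  dialect: TableDialect) -> AnalytePanel:
    def cell(name: str) -> str:
        return row[idx[name]].strip() if name in idx else ""

    age = _parse_number(cell("age"), dialect)
    if age is None:
        raise ValueError("age is missing")
    sex_token = cell("sex")
    labs = {}
    for name in ("hemoglobin", "ferritin", "tsat", "pth"):
        labs[name] = _parse_number(cell(name), dialect) if name in idx else None
    return AnalytePanel(
        patient_id=cell("patient_id"),
        specimen_date=datetime.date.fromisoformat(cell("specimen_date")),
        age=age,
        sex=Sex.parse(sex_token) if sex_token else Sex.FEMALE,
        **labs,
    )


def _format_number(value: float | None, dialect: TableDialect) -> str:
    if value is None:
        return ""
    text = repr(float(value))
    if text.endswith(".0"):
        text = text[:-2]
    return text.replace(".", dialect.decimal_mark)


def write_cohort_table(
    panels: Iterable[AnalytePanel],
    dest: "str | Path | TextIO",
    dialect: TableDialect = TableDialect(),
) -> None:
    """Write panels as a delimited table (inverse of :func:`read_cohort_table`)."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8", newline="") as fh:
            write_cohort_table(panels, fh, dialect)
            return
    writer = csv.writer(dest, delimiter=dialect.separator, lineterminator="\n")
    writer.writerow(COLUMNS)
    for p in panels:
        writer.writerow([
            p.patient_id,
            p.specimen_date.isoformat(),
            str(p.age),
            p.sex.value,
            _format_number(p.hemoglobin, dialect),
            _format_number(p.ferritin, dialect),
            _format_number(p.tsat, dialect),
            _format_number(p.pth, dialect),
        ])


def first_record_per_patient(records: Iterable[AnalytePanel]) -> list[AnalytePanel]:
    """Keep exactly one record per patient: earliest specimen_date.

    Ties on the date are broken by input order (first seen wins); output
    preserves the order in which patients first appear and is guaranteed
    duplicate-free.
    """
    best: dict[str, AnalytePanel] = {}
    for panel in records:
        kept = best.get(panel.patient_id)
        if kept is None or panel.specimen_date < kept.specimen_date:
            best[panel.patient_id] = panel
    return list(best.values())


def apply_filters(
    records: Sequence[AnalytePanel],
) -> tuple[list[AnalytePanel], IngestReport]:
    """Complete-case eligibility filtering with a conservation audit.

    Applies :func:`~anemia_cdss.knowledge.eligibility_filter` to each
    (deduplicated) record; the eligible and excluded sets partition the
    input and the per-reason exclusion tallies account exactly for the
    difference.  No imputation ever happens.
    """
    eligible: list[AnalytePanel] = []
    exclusions: dict[str, int] = {}
    for panel in records:
        outcome: EligibilityOutcome = eligibility_filter(panel)
        if outcome.eligible:
            eligible.append(panel)
        else:
            reason = outcome.reason.value
            exclusions[reason] = exclusions.get(reason, 0) + 1
    report = IngestReport(
        n_input=len(records),
        n_after_dedup=len(records),
        n_eligible=len(eligible),
        exclusions=exclusions,
    )
    report.validate()
    return eligible, report


def ingest_cohort(
    source: "str | Path | TextIO",
    dialect: TableDialect = TableDialect(),
    date_window: tuple[datetime.date, datetime.date] | None = None,
) -> tuple[list[AnalytePanel], IngestReport]:
    """Full funnel: read -> optional date window -> dedup -> eligibility filter."""
    panels, issues = read_cohort_table(source, dialect)
    n_input = len(panels)
    if date_window is not None:
        lo, hi = date_window
        panels = [p for p in panels if lo <= p.specimen_date <= hi]
    deduped = first_record_per_patient(panels)
    eligible, report = apply_filters(deduped)
    report.n_input = n_input
    report.issues = issues
    report.validate()
    return eligible, report


# ---------------------------------------------------------------------------
# HL7 v2 ORU^R01 subset
# ---------------------------------------------------------------------------

#: default observation-code table (LOINC -> analyte); configuration, not code
DEFAULT_CODE_MAP: dict[str, Analyte] = {
    "718-7": Analyte.HEMOGLOBIN,   # Hemoglobin [Mass/volume] in Blood
    "2276-4": Analyte.FERRITIN,    # Ferritin [Mass/volume] in Serum or Plasma
    "2502-3": Analyte.TSAT,        # Iron saturation in Serum or Plasma
    "2731-8": Analyte.PTH,         # Parathyrin.intact [Mass/volume]
}


def _hl7_date(token: str) -> datetime.date:
    m = re.match(r"^(\d{4})(\d{2})(\d{2})", token)
    if not m:
        raise MessageError(f"unparseable HL7 timestamp {token!r}")
    return datetime.date(int(m.group(1)), int(m.group(2)), int(m.group(3)))


def parse_hl7_oru(
    message: str,
    code_map: dict[str, Analyte] | None = None,
) -> tuple[AnalytePanel, list[str]]:
    """Parse a minimal pipe-delimited HL7 v2 ORU^R01 message into a panel.

    Supports one patient per message with MSH, PID, optional OBR, and
    numeric OBX segments.  Patient id comes from PID-3, sex from PID-8,
    age from the PID-7 birth date relative to the specimen date (OBR-7,
    falling back to MSH-7).  OBX-3 observation codes map to analytes via
    ``code_map`` (LOINC by default); unknown codes are ignored with an
    issue note; the same analyte code twice in one message makes the
    panel ambiguous and raises :class:`MessageError`.
    """
    if code_map is None:
        code_map = DEFAULT_CODE_MAP
    segments = [s.strip() for s in re.split(r"[\r\n]+", message or "") if s.strip()]
    if not segments:
        raise MessageError("empty HL7 message")
    by_type: dict[str, list[list[str]]] = {}
    for seg in segments:
        fields = seg.split("|")
        by_type.setdefault(fields[0], []).append(fields)
    if "MSH" not in by_type:
        raise MessageError("missing MSH segment")
    if "PID" not in by_type:
        raise MessageError("missing PID segment")

    def fld(fields: list[str], n: int, msh: bool = False) -> str:
        # MSH-1 is the field separator itself, so MSH indices shift by one
        i = n - 1 if msh else n
        return fields[i].split("^")[0].strip() if i < len(fields) else ""

    msh = by_type["MSH"][0]
    pid = by_type["PID"][0]
    patient_id = fld(pid, 3)
    if not patient_id:
        raise MessageError("PID-3 patient identifier is empty")
    specimen_token = ""
    if "OBR" in by_type:
        specimen_token = fld(by_type["OBR"][0], 7)
    if not specimen_token:
        specimen_token = fld(msh, 7, msh=True)
    if not specimen_token:
        raise MessageError("no specimen/message timestamp (OBR-7 or MSH-7)")
    specimen_date = _hl7_date(specimen_token)
    dob_token = fld(pid, 7)
    if not dob_token:
        raise MessageError("PID-7 birth date is required to derive age")
    dob = _hl7_date(dob_token)
    age = specimen_date.year - dob.year - (
        (specimen_date.month, specimen_date.day) < (dob.month, dob.day)
    )
    sex_token = fld(pid, 8) or "F"

    issues: list[str] = []
    values: dict[Analyte, float] = {}
    for obx in by_type.get("OBX", []):
        value_type = fld(obx, 2)
        code = fld(obx, 3)
        raw = fld(obx, 5)
        if value_type and value_type != "NM":
            issues.append(f"OBX {code!r}: non-numeric value type {value_type!r} ignored")
            continue
        analyte = code_map.get(code)
        if analyte is None:
            issues.append(f"OBX observation code {code!r} is not mapped; ignored")
            continue
        if analyte in values:
            raise MessageError(
                f"duplicate observation for {analyte.value!r} makes the panel ambiguous"
            )
        try:
            values[analyte] = float(raw)
        except ValueError:
            raise MessageError(f"OBX {code!r} carries non-numeric value {raw!r}")

    panel = AnalytePanel(
        patient_id=patient_id,
        specimen_date=specimen_date,
        age=age,
        sex=Sex.parse(sex_token),
        hemoglobin=values.get(Analyte.HEMOGLOBIN),
        ferritin=values.get(Analyte.FERRITIN),
        tsat=values.get(Analyte.TSAT),
        pth=values.get(Analyte.PTH),
    )
    return panel, issues
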