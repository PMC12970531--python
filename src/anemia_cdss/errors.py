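"""Exception hierarchy for the anemia CDSS pipeline."""


class CdssError(Exception):
    """Base class for all package errors."""


class MissingAnalyte(CdssError):
    """A rule or predicate referenced an analyte absent from the panel.

    Raised instead of returning a default truth value: a missing key
    analyte means the record belongs on the complete-case exclusion
    path, never that the predicate is silently false.
    """

    def __init__(self, analyte: str):
        self.analyte = str(analyte)
        super().__init__(f"analyte {self.analyte!r} is absent from the panel")


class RulesetConflict(CdssError):
    """Two same-tier classification rules fired on one panel."""


class ValidationError(CdssError):
    """A rule, predicate or panel failed structural validation."""


class NoRecommendation(CdssError):
    """No recommendation text exists for the requested label."""


class FormatError(CdssError):
    """A delimited table is missing mandatory columns or is unreadable."""


class MessageError(CdssError):
    """An HL7 v2 message is structurally unusable (no MSH/PID, ambiguous panel)."""


class SpecError(CdssError):
    """A synthetic group specification is inconsistent with its rule region."""


class ReportError(CdssError):
    """Writing a report artifact failed."""
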