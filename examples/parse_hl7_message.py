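"""Parse a minimal HL7 v2 ORU^R01 laboratory message into an analyte panel.

Observation codes (OBX-3) map to analytes through a configurable
LOINC/internal-code table; unknown codes are kept as issue notes rather
than errors.
"""

from anemia_cdss import parse_hl7_oru

message = "\r".join([
    "MSH|^~\\&|WinsisLab|Lab|CDSS|Renal|202303011200||ORU^R01|MSG001|P|2.5",
    "PID|1|P77|P77||Diaz^Ana||19630415|F",
    "OBR|1|||RenalPanel|||20230301",
    "OBX|1|NM|718-7^Hemoglobin^LN||10.4|g/dl",
    "OBX|2|NM|2276-4^Ferritin^LN||369.2|ng/ml",
    "OBX|3|NM|2502-3^Transferrin saturation^LN||14.1|%",
    "OBX|4|NM|9999-9^Unmapped test^LN||5|u",
])

panel, issues = parse_hl7_oru(message)
print(f"patient {panel.patient_id}, age {panel.age}, sex {panel.sex.value}")
print(f"Hb {panel.hemoglobin} g/dl, ferritin {panel.ferritin} ng/ml, "
      f"TSAT {panel.tsat} %, PTH {panel.pth}")
for issue in issues:
    print("issue:", issue)
# Age is derived from the PID-7 birth date at the specimen date; the
# unmapped 9999-9 observation is ignored with an issue note, and PTH
# stays absent (None) because no mapped PTH observation was present.
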