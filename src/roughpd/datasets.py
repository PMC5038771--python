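"""Small built-in datasets: the published two-patient examination extract.

The study examined 10 DBS-implanted Parkinson's patients in four
treatment sessions (S1 med off / stim off ... S4 med on / stim on);
the publicly printed extract covers two patients (8 examinations) with
neurological scores and reflexive-saccade parameters.  It is the worked
example used throughout the tests: its discretization under the
published cuts and the decision rule induced from its last row are both
known outputs.
"""

from __future__ import annotations

from .tables import AttributeSpec, DecisionTable, InformationTable, as_decision_table

__all__ = [
    "EXTRACT_SCHEMA",
    "patient_extract",
    "extract_decision_table",
    "EXTRACT_CUTS",
    "EXTRACT_DECISION_CUTS",
]

#: Schema of the printed extract: patient id and session are nominal,
#: scores and saccade parameters numeric.
EXTRACT_SCHEMA = [
    AttributeSpec("Pat", "nominal", "condition", ""),
    AttributeSpec("age", "numeric", "condition", "years"),
    AttributeSpec("sex", "nominal", "condition", "0=female,1=male"),
    AttributeSpec("t_dur", "numeric", "condition", "years"),
    AttributeSpec("Sess", "nominal", "condition", "S1-S4"),
    AttributeSpec("UPDRS", "numeric", "condition", "score points"),
    AttributeSpec("HYsc", "numeric", "condition", "stage"),
    AttributeSpec("SccDur", "numeric", "condition", "ms"),
    AttributeSpec("SccLat", "numeric", "condition", "ms"),
    AttributeSpec("SccAmp", "numeric", "condition", "deg"),
    AttributeSpec("SccVel", "numeric", "condition", "deg/s"),
]

# One row per examination: patient, age, sex, disease duration, session,
# total UPDRS, Hoehn-Yahr, saccade duration/latency/amplitude/velocity.
# Two rows share patient 28 x session 2 (repeated measurement).
_ROWS = [
    ("28", 54, "1", 8, "1", 58, 2.0, 43, 402, 12, 566.9),
    ("28", 54, "1", 8, "2", 40, 1.0, 46, 297, 11, 474.5),
    ("28", 54, "1", 8, "2", 40, 1.0, 49, 227, 10, 431.2),
    ("28", 54, "1", 8, "4", 16, 1.0, 47, 198, 9, 376.2),
    ("38", 56, "0", 11, "1", 49, 2.5, 42, 285, 14, 675.2),
    ("38", 56, "0", 11, "2", 22, 1.5, 48, 217, 12, 509.7),
    ("38", 56, "0", 11, "3", 37, 2.5, 43, 380, 14, 638.9),
    ("38", 56, "0", 11, "4", 12, 1.5, 45, 187, 10, 482.6),
]

#: Published condition cuts of the worked example (disease duration and
#: Hoehn-Yahr received no cuts, i.e. were starred as not significant).
EXTRACT_CUTS = {
    "age": [55.0],
    "t_dur": [],
    "HYsc": [],
    "SccDur": [45.5],
    "SccLat": [260.0],
    "SccAmp": [10.5],
    "SccVel": [],
}

#: Published binning of the total-UPDRS decision into four classes.
EXTRACT_DECISION_CUTS = [14.0, 22.5, 55.0]


def patient_extract() -> InformationTable:
    """The 8 printed examination records as an information table."""
    records = []
    for row in _ROWS:
        rec = {}
        for spec, v in zip(EXTRACT_SCHEMA, row):
            rec[spec.name] = float(v) if spec.kind == "numeric" else str(v)
        records.append(rec)
    return InformationTable(EXTRACT_SCHEMA, records)


def extract_decision_table(decision: str = "UPDRS") -> DecisionTable:
    """The extract re-roled as a decision table (default decision UPDRS)."""
    return as_decision_table(patient_extract(), decision)
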