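"""Patient-level cohort data model, CSV round-trip, and record validation.

A cohort is a flat table of one row per iNPH patient: demographics and
clinical history, the paired pre/post tap-test assessments, the structural
imaging profile, the treating center, and pre/postoperative symptom-severity
scores used to grade shunt response.

CSV dialect: comma separated, UTF-8, dot decimal, header required, booleans
encoded 0/1, missing optional fields as empty cells.  The machine-readable
column dictionary ships as ``data/cohort_schema.json``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = [
    "TapAssessment",
    "ImagingProfile",
    "PatientRecord",
    "Violation",
    "SchemaError",
    "RowParseError",
    "CohortValidationError",
    "read_cohort_csv",
    "write_cohort_csv",
    "validate_record",
    "cohort_to_frame",
    "frame_to_records",
]


class SchemaError(ValueError):
    """The CSV header does not match the expected column set."""


class RowParseError(ValueError):
    """A cell in a data row could not be parsed; carries the 1-based row number."""

    def __init__(self, row: int, column: str, message: str):
        self.row = row
        self.column = column
        super().__init__(f"row {row}, column '{column}': {message}")


class CohortValidationError(ValueError):
    """A parsed record violates a field invariant; names row and field."""

    def __init__(self, row: int, violations: list["Violation"]):
        self.row = row
        self.violations = violations
        detail = "; ".join(f"{v.field}: {v.rule}" for v in violations)
        super().__init__(f"row {row}: {detail}")


@dataclass(frozen=True)
class Violation:
    """One invariant breach: which field, which rule, human-readable message."""

    field: str
    rule: str
    message: str = ""


@dataclass
class TapAssessment:
    """Paired pre/post lumbar-tap assessments for the three response criteria.

    Gait by the 10 m walk test (time in seconds, step count), cognition by
    MMSE (0-30), urinary incontinence by patient self-rating (0-10, higher
    is worse).
    """

    pre_walk_time: float
    pre_walk_steps: int
    pre_mmse: int
    pre_urinary: int
    post_walk_time: float
    post_walk_steps: int
    post_mmse: int
    post_urinary: int


@dataclass
class ImagingProfile:
    """Structural MRI markers, already measured (no image handling here).

    Angles in degrees, widths in mm, indices dimensionless.  ``desh`` is the
    binary visual read of disproportionately enlarged subarachnoid-space
    hydrocephalus (tight high-convexity sulci with enlarged Sylvian fissures).
    """

    ei: float
    desh: bool
    ca: float
    z_ei: float
    bvr: float
    scca: float
    temporal_horn_left: float
    temporal_horn_right: float
    third_ventricle_width: float
    posterior_horn_ratio: float


@dataclass
class PatientRecord:
    """One subject: demographics, tap assessment, imaging, center, outcome."""

    id: str
    center_id: str
    age: float
    sex: str  # "male" | "female"
    lp_pressure: float  # lumbar puncture opening pressure, mmH2O
    disease_duration: float  # months
    symptom_gait: bool
    symptom_cognitive: bool
    symptom_urinary: bool
    comorb_cardiovascular: bool
    comorb_endocrine: bool
    comorb_neurological: bool
    tap: TapAssessment
    imaging: ImagingProfile
    preop_severity_score: int
    postop_severity_score: Optional[int] = None
    outcome_label: Optional[str] = None  # "responder" | "non_responder"


# Canonical flat column order.  Deterministic: writing is byte-stable.
_TAP_COLS = [f.name for f in dc_fields(TapAssessment)]
_IMG_COLS = [f.name for f in dc_fields(ImagingProfile)]
COLUMNS = (
    [
        "id",
        "center_id",
        "age",
        "sex",
        "lp_pressure",
        "disease_duration",
        "symptom_gait",
        "symptom_cognitive",
        "symptom_urinary",
        "comorb_cardiovascular",
        "comorb_endocrine",
        "comorb_neurological",
    ]
    + _TAP_COLS
    + _IMG_COLS
    + ["preop_severity_score", "postop_severity_score", "outcome_label"]
)

_BOOL_COLS = {
    "symptom_gait",
    "symptom_cognitive",
    "symptom_urinary",
    "comorb_cardiovascular",
    "comorb_endocrine",
    "comorb_neurological",
    "desh",
}
_INT_COLS = {
    "pre_walk_steps",
    "post_walk_steps",
    "pre_mmse",
    "post_mmse",
    "pre_urinary",
    "post_urinary",
    "preop_severity_score",
}
_STR_COLS = {"id", "center_id", "sex"}
_OPTIONAL_COLS = {"postop_severity_score", "outcome_label"}


def validate_record(record: PatientRecord) -> list[Violation]:
    """Check every field invariant; return all breaches (empty list = valid).

    Validation is total: any record yields a list, never an exception.
    """
    v: list[Violation] = []

    def bad(fieldname: str, rule: str, msg: str = "") -> None:
        v.append(Violation(fieldname, rule, msg))

    if not record.id:
        bad("id", "non-empty")
    if not record.center_id:
        bad("center_id", "non-empty")
    if not (isinstance(record.age, (int, float)) and record.age > 0):
        bad("age", "age > 0")
    if record.sex not in ("male", "female"):
        bad("sex", "sex in {male, female}")
    # normal-pressure inclusion criterion: CSF opening pressure 80-200 mmH2O
    if not (80 <= record.lp_pressure <= 200):
        bad("lp_pressure", "lp_pressure in [80, 200] mmH2O")
    if not record.disease_duration > 0:
        bad("disease_duration", "disease_duration > 0")

    t = record.tap
    for name in ("pre_walk_time", "pre_walk_steps", "post_walk_time", "post_walk_steps"):
        if not getattr(t, name) > 0:
            bad(name, f"{name} > 0")
    for name in ("pre_mmse", "post_mmse"):
        val = getattr(t, name)
        if not (0 <= val <= 30):
            bad(name, f"{name} in [0, 30]")
    for name in ("pre_urinary", "post_urinary"):
        val = getattr(t, name)
        if not (0 <= val <= 10):
            bad(name, f"{name} in [0, 10]")

    im = record.imaging
    if not (0 < im.ei < 1):
        bad("ei", "ei in (0, 1)")
    for name in ("ca", "scca"):
        val = getattr(im, name)
        if not (0 < val < 180):
            bad(name, f"{name} in (0, 180) degrees")
    for name in ("temporal_horn_left", "temporal_horn_right", "third_ventricle_width"):
        if getattr(im, name) < 0:
            bad(name, f"{name} >= 0 mm")
    for name in ("z_ei", "bvr", "posterior_horn_ratio"):
        if getattr(im, name) < 0:
            bad(name, f"{name} >= 0")

    if record.preop_severity_score < 0:
        bad("preop_severity_score", "preop_severity_score >= 0")
    if record.postop_severity_score is not None and record.postop_severity_score < 0:
        bad("postop_severity_score", "postop_severity_score >= 0")
    if record.outcome_label is not None and record.outcome_label not in (
        "responder",
        "non_responder",
    ):
        bad("outcome_label", "outcome_label in {responder, non_responder}")
    return v


def _record_to_row(r: PatientRecord) -> dict:
    row: dict = {}
    for c in COLUMNS:
        if c in _TAP_COLS:
            val = getattr(r.tap, c)
        elif c in _IMG_COLS:
            val = getattr(r.imaging, c)
        else:
            val = getattr(r, c)
        if c in _BOOL_COLS:
            val = int(bool(val))
        if val is None:
            val = ""
        row[c] = val
    return row


def cohort_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame in canonical column order."""
    return pd.DataFrame([_record_to_row(r) for r in records], columns=COLUMNS)


def _parse_cell(column: str, raw, rownum: int):
    if isinstance(raw, float) and math.isnan(raw):
        raw = ""
    text = str(raw).strip()
    if column in _OPTIONAL_COLS and text == "":
        return None
    if column in _STR_COLS:
        if text == "":
            raise RowParseError(rownum, column, "empty required cell")
        return text
    if column == "outcome_label":
        return text
    try:
        if column in _BOOL_COLS:
            iv = int(text)
            if iv not in (0, 1):
                raise ValueError("boolean cells must be 0 or 1")
            return bool(iv)
        if column in _INT_COLS or column == "postop_severity_score":
            return int(float(text))
        return float(text)
    except ValueError as exc:
        raise RowParseError(rownum, column, f"cannot parse {text!r}: {exc}") from exc


def frame_to_records(df: pd.DataFrame, validate: bool = True) -> list[PatientRecord]:
    """Parse a flat DataFrame into records, preserving row order.

    Row numbers in errors are 1-based data-row positions (header excluded).
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records: list[PatientRecord] = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        parsed = {c: _parse_cell(c, row[c], i) for c in COLUMNS}
        rec = PatientRecord(
            id=parsed["id"],
            center_id=parsed["center_id"],
            age=parsed["age"],
            sex=parsed["sex"],
            lp_pressure=parsed["lp_pressure"],
            disease_duration=parsed["disease_duration"],
            symptom_gait=parsed["symptom_gait"],
            symptom_cognitive=parsed["symptom_cognitive"],
            symptom_urinary=parsed["symptom_urinary"],
            comorb_cardiovascular=parsed["comorb_cardiovascular"],
            comorb_endocrine=parsed["comorb_endocrine"],
            comorb_neurological=parsed["comorb_neurological"],
            tap=TapAssessment(**{c: parsed[c] for c in _TAP_COLS}),
            imaging=ImagingProfile(**{c: parsed[c] for c in _IMG_COLS}),
            preop_severity_score=parsed["preop_severity_score"],
            postop_severity_score=parsed["postop_severity_score"],
            outcome_label=parsed["outcome_label"],
        )
        if validate:
            violations = validate_record(rec)
            if violations:
                raise CohortValidationError(i, violations)
        records.append(rec)
    return records


def read_cohort_csv(path, schema: Optional[dict] = None, validate: bool = True) -> list[PatientRecord]:
    """Read a cohort CSV into records.

    Parameters
    ----------
    path : path-like
    schema : optional mapping of canonical column name -> file column name,
        for files whose headers differ from the canonical dictionary.
    validate : raise :class:`CohortValidationError` on invariant breaches.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        rename = {v: k for k, v in schema.items()}
        missing = [src for src in rename if src not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = df.rename(columns=rename)
    return frame_to_records(df, validate=validate)


def write_cohort_csv(records: list[PatientRecord], path) -> None:
    """Write records in canonical column order; deterministic byte-for-byte."""
    df = cohort_to_frame(records)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")
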