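"""Patient-level data model for colorectal cancer surgery cohorts.

A cohort is represented in memory as a :class:`pandas.DataFrame` with one row
per surgical patient and the columns listed in :data:`COLUMN_ORDER`
(the "cohort table" layout written and read by :mod:`opmort.io`).  The
:class:`PatientRecord` dataclass is the record-level view of one row; any
clinical field may be missing (``None`` in a record, ``NaN``/``NA`` in a
frame).  The two mortality outcomes are plain booleans and are never missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Any, Iterable, Optional

import numpy as np
import pandas as pd

#: Allowed levels for every categorical clinical variable, lowest-risk first.
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "tumor_site": ("colon", "rectum"),
    "heart_failure": ("none_or_mild", "moderate", "severe"),
    "respiratory_status": (
        "no_dyspnoea",
        "dyspnoea_on_exertion",
        "limiting_dyspnoea",
        "dyspnoea_at_rest",
    ),
    "ecg": ("normal", "atrial_fibrillation", "other_abnormal"),
    "urgency": ("scheduled", "urgent", "emergency"),
    "operative_severity": ("minor", "moderate", "major", "complex_major"),
    "peritoneal_contamination": (
        "none_or_serous",
        "local_pus",
        "free_pus_faeces_blood",
    ),
    "dukes_stage": ("A_B", "C", "D"),
}

#: Numeric clinical variables with their units.
NUMERIC_FIELDS: dict[str, str] = {
    "age": "years",
    "sbp": "mmHg",
    "heart_rate": "beats/min",
    "glasgow_coma_score": "points (3-15)",
    "urea": "mmol/L",
    "haemoglobin": "g/dL",
    "leucocytes": "x10^12/L",
    "sodium": "mmol/L",
    "potassium": "mmol/L",
    "n_procedures": "count",
    "blood_loss": "mL",
}

BOOLEAN_FIELDS = ("weight_loss_gt10pct", "neuro_comorbidity")
OUTCOME_FIELDS = ("death_inhospital", "death_30day")

CLINICAL_FIELDS: tuple[str, ...] = tuple(CATEGORICAL_LEVELS) + tuple(
    NUMERIC_FIELDS
) + BOOLEAN_FIELDS

COLUMN_ORDER: tuple[str, ...] = (
    "patient_id",
    "age",
    "sex",
    "tumor_site",
    "heart_failure",
    "respiratory_status",
    "sbp",
    "heart_rate",
    "glasgow_coma_score",
    "urea",
    "haemoglobin",
    "leucocytes",
    "sodium",
    "potassium",
    "ecg",
    "weight_loss_gt10pct",
    "neuro_comorbidity",
    "urgency",
    "operative_severity",
    "n_procedures",
    "blood_loss",
    "peritoneal_contamination",
    "dukes_stage",
    "death_inhospital",
    "death_30day",
)

# Out-of-range magnitudes that suggest a unit mix-up (no silent conversion is
# ever applied; the reader only warns).  Urea is mmol/L: values above ~60
# look like mg/dL; haemoglobin is g/dL: values above 30 look like g/L.
UNIT_PLAUSIBILITY: dict[str, tuple[float, str]] = {
    "urea": (60.0, "urea looks like mg/dL; expected mmol/L"),
    "haemoglobin": (30.0, "haemoglobin looks like g/L; expected g/dL"),
    "sodium": (200.0, "sodium outside physiological mmol/L range"),
}


class RecordError(ValueError):
    """Invalid value on a patient record."""


@dataclass
class PatientRecord:
    """One surgical patient: clinical variables plus the two death outcomes.

    Clinical fields set to ``None`` are treated as missing; the outcome flags
    are independent booleans (a death in hospital after day 30 sets only
    ``death_inhospital``; a post-discharge death within 30 days sets only
    ``death_30day``).
    """

    patient_id: str
    age: Optional[float] = None
    sex: Optional[str] = None
    tumor_site: Optional[str] = None
    heart_failure: Optional[str] = None
    respiratory_status: Optional[str] = None
    sbp: Optional[float] = None
    heart_rate: Optional[float] = None
    glasgow_coma_score: Optional[float] = None
    urea: Optional[float] = None
    haemoglobin: Optional[float] = None
    leucocytes: Optional[float] = None
    sodium: Optional[float] = None
    potassium: Optional[float] = None
    ecg: Optional[str] = None
    weight_loss_gt10pct: Optional[bool] = None
    neuro_comorbidity: Optional[bool] = None
    urgency: Optional[str] = None
    operative_severity: Optional[str] = None
    n_procedures: Optional[float] = None
    blood_loss: Optional[float] = None
    peritoneal_contamination: Optional[str] = None
    dukes_stage: Optional[str] = None
    death_inhospital: bool = False
    death_30day: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, levels in CATEGORICAL_LEVELS.items():
            value = getattr(self, name)
            if value is not None and value not in levels:
                raise RecordError(
                    f"{name}={value!r} not one of {levels} "
                    f"(patient {self.patient_id})"
                )
        if self.age is not None and not self.age > 0:
            raise RecordError(f"age must be positive (patient {self.patient_id})")
        for name in ("sbp", "heart_rate", "urea", "haemoglobin"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise RecordError(
                    f"{name} must be non-negative (patient {self.patient_id})"
                )
        gcs = self.glasgow_coma_score
        if gcs is not None and not (3 <= gcs <= 15):
            raise RecordError(
                f"glasgow_coma_score must lie in 3..15 (patient {self.patient_id})"
            )
        if self.n_procedures is not None and self.n_procedures < 1:
            raise RecordError(
                f"n_procedures must be >= 1 (patient {self.patient_id})"
            )

    def is_missing(self, name: str) -> bool:
        value = getattr(self, name)
        return value is None or (isinstance(value, float) and np.isnan(value))

    def to_dict(self) -> dict[str, Any]:
        return {name: getattr(self, name) for name in COLUMN_ORDER}


def _clean(value: Any) -> Any:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if value is pd.NA or value is pd.NaT:
        return None
    if isinstance(value, (np.floating, np.integer)):
        return float(value)
    if isinstance(value, np.bool_):
        return bool(value)
    return value


def record_from_row(row: "pd.Series | dict[str, Any]") -> PatientRecord:
    data = {name: _clean(row.get(name)) for name in COLUMN_ORDER if name in row}
    data.setdefault("patient_id", str(row.get("patient_id", "")))
    data["patient_id"] = str(data["patient_id"])
    for name in OUTCOME_FIELDS:
        data[name] = bool(data.get(name) or False)
    return PatientRecord(**data)


def cohort_to_frame(cohort: Iterable[PatientRecord]) -> pd.DataFrame:
    """Pack records into the standard cohort table (one row per patient)."""
    rows = [rec.to_dict() for rec in cohort]
    frame = pd.DataFrame(rows, columns=list(COLUMN_ORDER))
    if len(frame) == 0:
        frame = pd.DataFrame(columns=list(COLUMN_ORDER))
    return frame


def frame_to_cohort(frame: pd.DataFrame) -> list[PatientRecord]:
    return [record_from_row(row) for _, row in frame.iterrows()]


def as_frame(cohort: "pd.DataFrame | Iterable[PatientRecord]") -> pd.DataFrame:
    """Accept either cohort representation and return the DataFrame form."""
    if isinstance(cohort, pd.DataFrame):
        missing = [c for c in COLUMN_ORDER if c not in cohort.columns]
        if missing:
            raise RecordError(f"cohort table lacks columns: {missing}")
        return cohort
    return cohort_to_frame(cohort)
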