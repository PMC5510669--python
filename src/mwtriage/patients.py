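"""Patient-characteristics table and cohort summary statistics.

The packaged fixture ``table2_patients.csv`` mirrors the published
characteristics of the 20 surgical hematoma patients: age, sex, left/right
hematoma volume in mL (absent for the side without a hematoma), CT
attenuation in Hounsfield units (an interval for inhomogeneous hematomas),
and midline shift in mm.

A patient's *total* hematoma volume sums left and right sides (absent side
counts 0 mL); a patient is *bilateral* when both sides carry volume.
Attenuation is retained as a range, never collapsed to a midpoint, and no
attenuation summary is computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "PatientRecord",
    "CohortSummary",
    "load_patient_table",
    "write_patient_table",
    "cohort_summary",
    "parse_attenuation",
    "packaged_table_path",
]

_HEADER = [
    "patient_id",
    "age",
    "sex",
    "vol_right_ml",
    "vol_left_ml",
    "attenuation_lo_hu",
    "attenuation_hi_hu",
    "midline_shift_mm",
]


@dataclass(frozen=True)
class PatientRecord:
    """One patient row; ``vol_right``/``vol_left`` are None for absent sides."""

    patient_id: str
    age: float
    sex: str
    vol_right: float | None
    vol_left: float | None
    attenuation_lo: float
    attenuation_hi: float
    midline_shift: float

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.vol_right is None and self.vol_left is None:
            raise ValueError("at least one hematoma volume must be present")
        for v in (self.vol_right, self.vol_left):
            if v is not None and v < 0:
                raise ValueError("volumes must be non-negative")
        if self.attenuation_lo > self.attenuation_hi:
            raise ValueError("attenuation_lo must not exceed attenuation_hi")
        if self.midline_shift < 0:
            raise ValueError("midline_shift must be non-negative")

    @property
    def total_volume(self) -> float:
        return (self.vol_right or 0.0) + (self.vol_left or 0.0)

    @property
    def bilateral(self) -> bool:
        return self.vol_right is not None and self.vol_left is not None


@dataclass(frozen=True)
class CohortSummary:
    n: int
    mean_age: float
    age_range: tuple[float, float]
    n_female: int
    n_male: int
    mean_total_volume: float  # mL, rounded half away from zero
    n_bilateral: int
    mean_midline_shift: float


def parse_attenuation(cell: str) -> tuple[float, float]:
    """Parse an attenuation cell: ``"22-49"`` (or en-dash) -> (22, 49); ``"26"`` -> (26, 26)."""
    text = str(cell).strip().replace("–", "-")
    if "-" in text:
        lo, hi = text.split("-", 1)
        return float(lo), float(hi)
    v = float(text)
    return v, v


def _absent(cell) -> bool:
    if cell is None:
        return True
    text = str(cell).strip()
    return text in ("", "-", "–", "nan")


def packaged_table_path() -> Path:
    """Path of the packaged patient-characteristics fixture."""
    return Path(resources.files("mwtriage.data") / "table2_patients.csv")


def load_patient_table(path: str | Path | None = None) -> list[PatientRecord]:
    """Load and validate a patient table; defaults to the packaged fixture.

    Accepts either separate ``attenuation_lo_hu``/``attenuation_hi_hu``
    columns or a single ``attenuation_hu`` column holding ``"lo-hi"`` or
    single-value cells.  Absent volumes may be empty cells or a dash.
    Validation errors name the offending row and field.
    """
    path = Path(path) if path is not None else packaged_table_path()
    df = pd.read_csv(path, dtype=str)
    combined = "attenuation_hu" in df.columns
    required = {"patient_id", "age", "sex", "vol_right_ml", "vol_left_ml", "midline_shift_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        rowno = i + 2  # 1-based, after header
        try:
            if combined:
                att_lo, att_hi = parse_attenuation(row["attenuation_hu"])
            else:
                att_lo = float(row["attenuation_lo_hu"])
                att_hi = float(row["attenuation_hi_hu"])
            rec = PatientRecord(
                patient_id=str(row["patient_id"]),
                age=float(row["age"]),
                sex=str(row["sex"]).strip(),
                vol_right=None if _absent(row["vol_right_ml"]) else float(row["vol_right_ml"]),
                vol_left=None if _absent(row["vol_left_ml"]) else float(row["vol_left_ml"]),
                attenuation_lo=att_lo,
                attenuation_hi=att_hi,
                midline_shift=float(row["midline_shift_mm"]),
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: row {rowno}: {exc}") from exc
        records.append(rec)
    if not records:
        raise ValueError(f"{path}: no patient records")
    return records


def write_patient_table(records: list[PatientRecord], path: str | Path) -> None:
    """Write records back to the documented CSV header (lossless round trip)."""

    def fmt(v: float | None) -> str:
        if v is None:
            return ""
        return str(int(v)) if float(v).is_integer() else str(v)

    rows = [
        {
            "patient_id": r.patient_id,
            "age": fmt(r.age),
            "sex": r.sex,
            "vol_right_ml": fmt(r.vol_right),
            "vol_left_ml": fmt(r.vol_left),
            "attenuation_lo_hu": fmt(r.attenuation_lo),
            "attenuation_hi_hu": fmt(r.attenuation_hi),
            "midline_shift_mm": fmt(r.midline_shift),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_HEADER).to_csv(path, index=False)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def cohort_summary(records: list[PatientRecord]) -> CohortSummary:
    """Cohort summary: mean age (1 decimal), mean total volume (nearest mL), counts."""
    if not records:
        raise ValueError("no records to summarize")
    ages = [r.age for r in records]
    totals = [r.total_volume for r in records]
    shifts = [r.midline_shift for r in records]
    n_female = sum(r.sex == "F" for r in records)
    return CohortSummary(
        n=len(records),
        mean_age=round(sum(ages) / len(ages), 1),
        age_range=(min(ages), max(ages)),
        n_female=n_female,
        n_male=len(records) - n_female,
        mean_total_volume=float(_round_half_away(sum(totals) / len(totals))),
        n_bilateral=sum(r.bilateral for r in records),
        mean_midline_shift=round(sum(shifts) / len(shifts), 1),
    )
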