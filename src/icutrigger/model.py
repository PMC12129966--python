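"""Domain model and delimited-text interchange for ICU patient records.

The surveillance pipeline operates on one ICU *stay* per patient: demographics
and outcome, a time-stamped laboratory series, medication courses with their
administrations, structured clinical-note events, and (cohort-wide) a log of
spontaneous ADR reports. Five flat UTF-8 CSV files carry a cohort on disk:

    patients.csv              patient_id,unit,sex,age,admit_time,discharge_time,outcome
    labs.csv                  patient_id,timestamp,analyte,value
    medications.csv           patient_id,drug_name,atc_code,start_time,stop_time,intended_end_time,scheduled,route
    administrations.csv       patient_id,drug_name,timestamp
    notes.csv                 patient_id,timestamp,kind,text
    spontaneous_reports.csv   patient_id,report_date,drug_name,reaction_text

Timestamps are ISO-8601; hospital days are 1-based calendar days (the
admission calendar day is day 1). Readers validate every invariant and
collect violations with line references instead of silently dropping rows.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "Unit",
    "Sex",
    "Outcome",
    "NoteKind",
    "Analyte",
    "LabResult",
    "MedicationCourse",
    "NoteEvent",
    "SpontaneousReport",
    "PatientRecord",
    "Cohort",
    "Violation",
    "Exclusion",
    "LoadResult",
    "length_of_stay",
    "los_whole_days",
    "hospital_day",
    "screen_eligibility",
    "read_cohort",
    "write_cohort",
    "COHORT_FILES",
]

ATC_PATTERN = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")


class Unit(str, Enum):
    G_ICU = "G-ICU"
    C19_ICU = "C19-ICU"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Outcome(str, Enum):
    DEATH = "death"
    DISCHARGE = "discharge"


class NoteKind(str, Enum):
    SKIN_RASH = "SKIN_RASH"
    PATIENT_FALL = "PATIENT_FALL"
    OVER_SEDATION = "OVER_SEDATION"
    OTHER = "OTHER"


class Analyte(str, Enum):
    """Laboratory/vital analytes, each with fixed units."""

    PTT_s = "PTT_s"
    INR = "INR"
    GLUCOSE_mg_dL = "GLUCOSE_mg_dL"
    SODIUM_mEq_L = "SODIUM_mEq_L"
    POTASSIUM_mmol_L = "POTASSIUM_mmol_L"
    PLATELETS_per_uL = "PLATELETS_per_uL"
    HEMOGLOBIN_g_dL = "HEMOGLOBIN_g_dL"
    HEMATOCRIT_pct = "HEMATOCRIT_pct"
    BUN_mg_dL = "BUN_mg_dL"
    CREATININE_mg_dL = "CREATININE_mg_dL"
    BILIRUBIN_mg_dL = "BILIRUBIN_mg_dL"
    PAO2_FIO2_ratio = "PAO2_FIO2_ratio"
    GCS_points = "GCS_points"
    MAP_mmHg = "MAP_mmHg"


@dataclass(frozen=True)
class LabResult:
    timestamp: datetime
    analyte: Analyte
    value: float

    def check(self) -> list[str]:
        problems = []
        if not math.isfinite(self.value) or self.value < 0:
            problems.append(f"{self.analyte.value} value {self.value} not finite/non-negative")
        if self.analyte is Analyte.GCS_points and not (3 <= self.value <= 15):
            problems.append(f"GCS {self.value} outside [3, 15]")
        if self.analyte is Analyte.MAP_mmHg and self.value >= 300:
            problems.append(f"MAP {self.value} implausible (>= 300 mmHg)")
        return problems


@dataclass
class MedicationCourse:
    drug_name: str
    atc_code: str
    start_time: datetime
    stop_time: datetime | None
    intended_end_time: datetime | None
    scheduled: bool
    administrations: list[datetime] = field(default_factory=list)
    route: str = "IV"

    def check(self) -> list[str]:
        problems = []
        if self.atc_code and not ATC_PATTERN.match(self.atc_code):
            problems.append(f"ATC code {self.atc_code!r} malformed for {self.drug_name}")
        if self.stop_time is not None and self.stop_time < self.start_time:
            problems.append(f"{self.drug_name}: stop before start")
        for ts in self.administrations:
            if ts < self.start_time or (self.stop_time is not None and ts > self.stop_time):
                problems.append(f"{self.drug_name}: administration {ts.isoformat()} outside course")
        return problems

    def active_on_day(self, record: "PatientRecord", day: int) -> bool:
        """True if the course overlaps the given 1-based hospital day."""
        day_start = datetime.combine(record.admit_time.date(), datetime.min.time()) + timedelta(days=day - 1)
        day_end = day_start + timedelta(days=1)
        stop = self.stop_time or record.discharge_time
        return self.start_time < day_end and stop >= day_start


@dataclass(frozen=True)
class NoteEvent:
    timestamp: datetime
    kind: NoteKind
    text: str = ""


@dataclass(frozen=True)
class SpontaneousReport:
    patient_id: str
    report_date: datetime
    drug_name: str
    reaction_text: str


@dataclass
class PatientRecord:
    patient_id: str
    unit: Unit
    sex: Sex
    age: int
    admit_time: datetime
    discharge_time: datetime
    outcome: Outcome
    labs: list[LabResult] = field(default_factory=list)
    medications: list[MedicationCourse] = field(default_factory=list)
    notes: list[NoteEvent] = field(default_factory=list)

    def check(self) -> list[str]:
        """Return invariant violations (empty list when the record is valid)."""
        problems = []
        if self.discharge_time <= self.admit_time:
            problems.append("discharge_time not after admit_time")
        for lab in self.labs:
            problems.extend(lab.check())
            if not self._in_stay(lab.timestamp):
                problems.append(f"lab {lab.analyte.value} at {lab.timestamp.isoformat()} outside stay")
        for course in self.medications:
            problems.extend(course.check())
            if not self._in_stay(course.start_time):
                problems.append(f"course {course.drug_name} starts outside stay")
        for note in self.notes:
            if not self._in_stay(note.timestamp):
                problems.append(f"note {note.kind.value} at {note.timestamp.isoformat()} outside stay")
        return problems

    def _in_stay(self, ts: datetime) -> bool:
        return self.admit_time <= ts <= self.discharge_time

    @property
    def los_days(self) -> float:
        return length_of_stay(self)

    def sorted_labs(self, analyte: Analyte) -> list[LabResult]:
        return sorted((l for l in self.labs if l.analyte is analyte), key=lambda l: l.timestamp)


@dataclass
class Cohort:
    records: list[PatientRecord] = field(default_factory=list)
    spontaneous_reports: list[SpontaneousReport] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient_id in cohort")


@dataclass(frozen=True)
class Violation:
    file: str
    line: int  # 1-based data line (header = line 1)
    message: str


@dataclass(frozen=True)
class Exclusion:
    patient_id: str
    reason: str


@dataclass
class LoadResult:
    cohort: Cohort
    violations: list[Violation]
    exclusions: list[Exclusion]


def length_of_stay(record: PatientRecord) -> float:
    """Length of stay in fractional days."""
    return (record.discharge_time - record.admit_time).total_seconds() / 86400.0


def los_whole_days(record: PatientRecord) -> int:
    """Length of stay in whole days, as reported in summaries.

    The ceiling of the fractional stay: a 25-hour stay counts as a full day
    of exposure (2 calendar days of observation never round down to 0).
    """
    return max(1, math.ceil(length_of_stay(record) - 1e-9))


def hospital_day(record: PatientRecord, ts: datetime) -> int:
    """1-based calendar hospital day of a timestamp (admission day = 1)."""
    return (ts.date() - record.admit_time.date()).days + 1


def screen_eligibility(records: Iterable[PatientRecord]) -> tuple[list[PatientRecord], list[Exclusion]]:
    """Apply the cohort inclusion criteria.

    Adults (>18 years), admitted for more than 24 h, with at least one
    prescribed medication. Failing records are excluded with a reason, not
    rejected with an error.
    """
    kept: list[PatientRecord] = []
    excluded: list[Exclusion] = []
    for rec in records:
        if rec.age <= 18:
            excluded.append(Exclusion(rec.patient_id, f"age {rec.age} <= 18"))
        elif length_of_stay(rec) <= 1.0:
            excluded.append(Exclusion(rec.patient_id, f"stay {length_of_stay(rec) * 24:.1f} h <= 24 h"))
        elif not rec.medications:
            excluded.append(Exclusion(rec.patient_id, "no prescribed medication"))
        else:
            kept.append(rec)
    return kept, excluded


# ---------------------------------------------------------------------------
# CSV interchange

COHORT_FILES = (
    "patients.csv",
    "labs.csv",
    "medications.csv",
    "administrations.csv",
    "notes.csv",
    "spontaneous_reports.csv",
)

_HEADERS = {
    "patients.csv": ["patient_id", "unit", "sex", "age", "admit_time", "discharge_time", "outcome"],
    "labs.csv": ["patient_id", "timestamp", "analyte", "value"],
    "medications.csv": [
        "patient_id", "drug_name", "atc_code", "start_time", "stop_time",
        "intended_end_time", "scheduled", "route",
    ],
    "administrations.csv": ["patient_id", "drug_name", "timestamp"],
    "notes.csv": ["patient_id", "timestamp", "kind", "text"],
    "spontaneous_reports.csv": ["patient_id", "report_date", "drug_name", "reaction_text"],
}

_ISO = "%Y-%m-%dT%H:%M:%S"


def _fmt(ts: datetime | None) -> str:
    return "" if ts is None else ts.strftime(_ISO)


def _parse_ts(raw: str) -> datetime | None:
    if raw is None or raw == "" or (isinstance(raw, float) and math.isnan(raw)):
        return None
    return datetime.fromisoformat(str(raw))


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write a cohort to the six-file CSV interchange layout.

    Returns the mapping file name -> written path. Output is readable by
    :func:`read_cohort` with identical semantic content (round-trip).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pat_rows, lab_rows, med_rows, adm_rows, note_rows, rep_rows = [], [], [], [], [], []
    for r in cohort.records:
        pat_rows.append([r.patient_id, r.unit.value, r.sex.value, r.age,
                         _fmt(r.admit_time), _fmt(r.discharge_time), r.outcome.value])
        for lab in sorted(r.labs, key=lambda l: (l.timestamp, l.analyte.value)):
            lab_rows.append([r.patient_id, _fmt(lab.timestamp), lab.analyte.value, repr(lab.value)])
        for m in r.medications:
            med_rows.append([r.patient_id, m.drug_name, m.atc_code, _fmt(m.start_time),
                             _fmt(m.stop_time), _fmt(m.intended_end_time),
                             "1" if m.scheduled else "0", m.route])
            for ts in m.administrations:
                adm_rows.append([r.patient_id, m.drug_name, _fmt(ts)])
        for n in sorted(r.notes, key=lambda n: n.timestamp):
            note_rows.append([r.patient_id, _fmt(n.timestamp), n.kind.value, n.text])
    for rep in cohort.spontaneous_reports:
        rep_rows.append([rep.patient_id, _fmt(rep.report_date), rep.drug_name, rep.reaction_text])

    tables = {
        "patients.csv": pat_rows,
        "labs.csv": lab_rows,
        "medications.csv": med_rows,
        "administrations.csv": adm_rows,
        "notes.csv": note_rows,
        "spontaneous_reports.csv": rep_rows,
    }
    written = {}
    for name, rows in tables.items():
        path = directory / name
        pd.DataFrame(rows, columns=_HEADERS[name]).to_csv(path, index=False, lineterminator="\n")
        written[name] = path
    return written


def read_cohort(directory: str | Path, *, screen: bool = True) -> LoadResult:
    """Read a cohort from the CSV interchange layout.

    Malformed rows become :class:`Violation` entries with their line number;
    records violating stay/eligibility invariants are excluded with a reason.
    A missing patients.csv is fatal; the auxiliary files may be absent (empty).
    """
    directory = Path(directory)
    pat_path = directory / "patients.csv"
    if not pat_path.exists():
        raise FileNotFoundError(f"missing required file: {pat_path}")
    violations: list[Violation] = []

    def load(name: str) -> pd.DataFrame:
        path = directory / name
        if not path.exists():
            return pd.DataFrame(columns=_HEADERS[name])
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if list(df.columns) != _HEADERS[name]:
            raise ValueError(f"{path}: header {list(df.columns)} != expected {_HEADERS[name]}")
        return df

    patients = load("patients.csv")
    labs = load("labs.csv")
    meds = load("medications.csv")
    adms = load("administrations.csv")
    notes = load("notes.csv")
    reports = load("spontaneous_reports.csv")

    records: dict[str, PatientRecord] = {}
    for i, row in patients.iterrows():
        line = i + 2  # header is line 1
        try:
            rec = PatientRecord(
                patient_id=row["patient_id"],
                unit=Unit(row["unit"]),
                sex=Sex(row["sex"]),
                age=int(row["age"]),
                admit_time=_parse_ts(row["admit_time"]),
                discharge_time=_parse_ts(row["discharge_time"]),
                outcome=Outcome(row["outcome"]),
            )
        except (ValueError, KeyError) as exc:
            violations.append(Violation("patients.csv", line, str(exc)))
            continue
        if rec.patient_id in records:
            violations.append(Violation("patients.csv", line, f"duplicate patient_id {rec.patient_id}"))
            continue
        records[rec.patient_id] = rec

    def resolve(name: str, line: int, pid: str) -> PatientRecord | None:
        rec = records.get(pid)
        if rec is None:
            violations.append(Violation(name, line, f"unknown patient_id {pid!r}"))
        return rec

    for i, row in labs.iterrows():
        line = i + 2
        rec = resolve("labs.csv", line, row["patient_id"])
        if rec is None:
            continue
        try:
            lab = LabResult(_parse_ts(row["timestamp"]), Analyte(row["analyte"]), float(row["value"]))
        except ValueError as exc:
            violations.append(Violation("labs.csv", line, str(exc)))
            continue
        problems = lab.check()
        if problems or not rec._in_stay(lab.timestamp):
            msg = "; ".join(problems) or f"timestamp outside stay of {rec.patient_id}"
            violations.append(Violation("labs.csv", line, msg))
            continue
        rec.labs.append(lab)

    course_index: dict[tuple[str, str], MedicationCourse] = {}
    for i, row in meds.iterrows():
        line = i + 2
        rec = resolve("medications.csv", line, row["patient_id"])
        if rec is None:
            continue
        try:
            course = MedicationCourse(
                drug_name=row["drug_name"],
                atc_code=row["atc_code"],
                start_time=_parse_ts(row["start_time"]),
                stop_time=_parse_ts(row["stop_time"]),
                intended_end_time=_parse_ts(row["intended_end_time"]),
                scheduled=row["scheduled"] in ("1", "true", "True"),
                route=row["route"],
            )
        except ValueError as exc:
            violations.append(Violation("medications.csv", line, str(exc)))
            continue
        problems = course.check()
        if problems:
            violations.append(Violation("medications.csv", line, "; ".join(problems)))
            continue
        rec.medications.append(course)
        course_index[(rec.patient_id, course.drug_name)] = course

    for i, row in adms.iterrows():
        line = i + 2
        course = course_index.get((row["patient_id"], row["drug_name"]))
        if course is None:
            violations.append(Violation("administrations.csv", line,
                                        f"no course for {row['drug_name']!r} of {row['patient_id']!r}"))
            continue
        ts = _parse_ts(row["timestamp"])
        course.administrations.append(ts)

    for i, row in notes.iterrows():
        line = i + 2
        rec = resolve("notes.csv", line, row["patient_id"])
        if rec is None:
            continue
        try:
            note = NoteEvent(_parse_ts(row["timestamp"]), NoteKind(row["kind"]), row["text"])
        except ValueError as exc:
            violations.append(Violation("notes.csv", line, str(exc)))
            continue
        if not rec._in_stay(note.timestamp):
            violations.append(Violation("notes.csv", line, "timestamp outside stay"))
            continue
        rec.notes.append(note)

    spontaneous = []
    for i, row in reports.iterrows():
        line = i + 2
        try:
            spontaneous.append(SpontaneousReport(row["patient_id"], _parse_ts(row["report_date"]),
                                                 row["drug_name"], row["reaction_text"]))
        except ValueError as exc:
            violations.append(Violation("spontaneous_reports.csv", line, str(exc)))

    # full-record invariant sweep (e.g. administrations outside course)
    accepted = []
    for rec in records.values():
        problems = rec.check()
        if problems:
            for p in problems:
                violations.append(Violation("patients.csv", 0, f"{rec.patient_id}: {p}"))
        else:
            accepted.append(rec)

    exclusions: list[Exclusion] = []
    if screen:
        accepted, exclusions = screen_eligibility(accepted)
    return LoadResult(Cohort(accepted, spontaneous), violations, exclusions)
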