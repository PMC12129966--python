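"""Shared fixtures: small hand-built records and session-scoped synthetic
cohorts (generated programmatically — no stored data files)."""

from __future__ import annotations

from datetime import datetime, timedelta

import pytest

from icutrigger.adjudication import adjudicate_cohort
from icutrigger.model import (Analyte, LabResult, MedicationCourse, NoteEvent, NoteKind,
                              Outcome, PatientRecord, Sex, Unit)
from icutrigger.synth import default_config, generate
from icutrigger.triggers import default_catalog, scan_cohort

ADMIT = datetime(2020, 3, 1, 0, 30)


def make_record(los_days: int = 10, labs=None, medications=None, notes=None,
                patient_id: str = "T0001", age: int = 60,
                unit: Unit = Unit.G_ICU) -> PatientRecord:
    """A minimal valid stay with optional event streams."""
    rec = PatientRecord(
        patient_id=patient_id, unit=unit, sex=Sex.FEMALE, age=age,
        admit_time=ADMIT, discharge_time=ADMIT + timedelta(days=los_days),
        outcome=Outcome.DISCHARGE,
        labs=list(labs or []), medications=list(medications or []),
        notes=list(notes or []),
    )
    if not rec.medications:
        rec.medications.append(MedicationCourse(
            drug_name="omeprazole", atc_code="A02BC01",
            start_time=ADMIT + timedelta(hours=8), stop_time=None,
            intended_end_time=None, scheduled=True))
    return rec


def lab(day: int, analyte: Analyte, value: float, hour: int = 10) -> LabResult:
    """A lab value on a 1-based hospital day of the standard test stay."""
    return LabResult(ADMIT.replace(hour=hour, minute=0) + timedelta(days=day - 1),
                     analyte, value)


def note(day: int, kind: NoteKind, text: str = "", hour: int = 14) -> NoteEvent:
    return NoteEvent(ADMIT.replace(hour=hour, minute=0) + timedelta(days=day - 1), kind, text)


def course(drug: str, start_day: int, stop_day: int | None, *, intended_day: int | None = None,
           scheduled: bool = True, admin_days=(), atc: str = "") -> MedicationCourse:
    start = ADMIT.replace(hour=9) + timedelta(days=start_day - 1)
    stop = None if stop_day is None else ADMIT.replace(hour=18) + timedelta(days=stop_day - 1)
    intended = (None if intended_day is None
                else ADMIT.replace(hour=18) + timedelta(days=intended_day - 1))
    return MedicationCourse(
        drug_name=drug, atc_code=atc, start_time=start, stop_time=stop,
        intended_end_time=intended, scheduled=scheduled,
        administrations=[ADMIT.replace(hour=10) + timedelta(days=d - 1) for d in admin_days])


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def study_cohort():
    """Default calibration (n = 135), the study-scale cohort."""
    cfg = default_config()
    cfg.seed = 0
    return generate(cfg)


@pytest.fixture(scope="session")
def study_hits(study_cohort, catalog):
    cohort, _ = study_cohort
    return scan_cohort(cohort.records, catalog)


@pytest.fixture(scope="session")
def study_adrs(study_cohort, study_hits, catalog):
    cohort, _ = study_cohort
    return adjudicate_cohort(cohort.records, study_hits, catalog)


@pytest.fixture(scope="session")
def large_cohort():
    """n = 2000 cohort for recovery checks."""
    cfg = default_config()
    cfg.n_patients = 2000
    cfg.seed = 20
    return generate(cfg)


@pytest.fixture(scope="session")
def large_hits(large_cohort, catalog):
    cohort, _ = large_cohort
    return scan_cohort(cohort.records, catalog)


@pytest.fixture(scope="session")
def large_adrs(large_cohort, large_hits, catalog):
    cohort, _ = large_cohort
    return adjudicate_cohort(cohort.records, large_hits, catalog)
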