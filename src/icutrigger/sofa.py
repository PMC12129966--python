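"""Sequential Organ Failure Assessment (SOFA) scoring.

Six organ systems — respiratory (PaO2/FiO2), coagulation (platelets),
hepatic (bilirubin), cardiovascular (mean arterial pressure), neurological
(Glasgow Coma Scale) and renal (creatinine) — are each scored 0 (normal) to
4 (severe dysfunction); the total ranges 0-24. Cut-points are the standard
published scale, packaged as an editable asset (``sofa_table.yaml``).

Two documented simplifications: the cardiovascular subscore uses MAP alone
(score 2 when the record flags vasopressor support, otherwise capped at 1),
and the renal subscore ignores urine output. Missing variables use
last-observation-carried-forward within the stay and score 0 before the
first observation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Mapping

from ._assets import load_asset
from .model import Analyte, PatientRecord

logger = logging.getLogger(__name__)

ORGANS = ("respiratory", "coagulation", "hepatic", "cardiovascular", "neurological", "renal")

VASOPRESSORS = {"dopamine", "epinephrine", "norepinephrine", "adrenaline", "noradrenaline"}

__all__ = ["ORGANS", "SofaAssessment", "SofaSummary", "sofa_subscore",
           "sofa_trajectory", "sofa_summary", "trajectory_frame"]


@dataclass(frozen=True)
class SofaAssessment:
    timestamp: datetime
    subscores: Mapping[str, int]

    @property
    def total(self) -> int:
        return sum(self.subscores.values())


@dataclass(frozen=True)
class SofaSummary:
    admission_score: int
    min_score: int
    max_score: int
    mean_score: float


def _table() -> dict:
    return load_asset("sofa_table.yaml")["organs"]


def sofa_subscore(organ: str, value: float | None, on_support: bool = False) -> int:
    """Score one organ system from its representative measurement.

    ``on_support`` marks active vasopressor support for the cardiovascular
    subscore. A missing value (``None``) scores 0 — the carry-forward policy
    of :func:`sofa_trajectory` means this only happens before the first
    observation of the stay.
    """
    table = _table()
    if organ not in table:
        raise KeyError(f"unknown SOFA organ {organ!r}; expected one of {ORGANS}")
    spec = table[organ]
    if organ == "cardiovascular" and on_support:
        return int(spec.get("on_support_score", 2))
    if value is None:
        return 0
    thresholds = spec["thresholds"]
    if spec["worse"] == "low":
        return sum(value < t for t in thresholds)
    return sum(value >= t for t in thresholds)


def sofa_trajectory(record: PatientRecord, interval_hours: int = 24) -> list[SofaAssessment]:
    """Assess SOFA at fixed intervals from admission.

    One assessment per interval boundary inside the stay, each using the
    most recent measurement per variable (LOCF). Variables never measured
    contribute 0 with a logged warning.
    """
    table = _table()
    organ_series: dict[str, list] = {}
    for organ, spec in table.items():
        series = record.sorted_labs(Analyte(spec["analyte"]))
        organ_series[organ] = series
        if not series:
            logger.warning("patient %s: no %s measurements; %s subscore defaults to 0",
                           record.patient_id, spec["analyte"], organ)
    support_windows = [
        (c.start_time, c.stop_time or record.discharge_time)
        for c in record.medications if c.drug_name.lower() in VASOPRESSORS
    ]
    assessments = []
    t = record.admit_time
    step = timedelta(hours=interval_hours)
    first = True
    while t < record.discharge_time:
        subs = {}
        on_support = any(s <= t <= e for s, e in support_windows)
        for organ in ORGANS:
            latest = None
            for lab in organ_series[organ]:
                if lab.timestamp <= t:
                    latest = lab.value
                else:
                    break
            if latest is None and first:
                # admission assessment: admission labs are charted within the
                # first interval, use the earliest one
                for lab in organ_series[organ]:
                    if lab.timestamp < t + step:
                        latest = lab.value
                    break
            subs[organ] = sofa_subscore(organ, latest,
                                        on_support=(organ == "cardiovascular" and on_support))
        assessments.append(SofaAssessment(t, subs))
        first = False
        t += step
    return assessments


def sofa_summary(trajectory: Iterable[SofaAssessment]) -> SofaSummary:
    """Per-stay summary: admission (first), minimum, maximum and mean total."""
    totals = [a.total for a in trajectory]
    if not totals:
        raise ValueError("cannot summarize an empty SOFA trajectory")
    return SofaSummary(
        admission_score=totals[0],
        min_score=min(totals),
        max_score=max(totals),
        mean_score=sum(totals) / len(totals),
    )


def trajectory_frame(record: PatientRecord, interval_hours: int = 24):
    """SOFA trajectory as rows for the CSV export
    (patient_id,timestamp,resp,coag,hepatic,cardio,neuro,renal,total)."""
    rows = []
    for a in sofa_trajectory(record, interval_hours):
        rows.append({
            "patient_id": record.patient_id,
            "timestamp": a.timestamp.isoformat(),
            "resp": a.subscores["respiratory"],
            "coag": a.subscores["coagulation"],
            "hepatic": a.subscores["hepatic"],
            "cardio": a.subscores["cardiovascular"],
            "neuro": a.subscores["neurological"],
            "renal": a.subscores["renal"],
            "total": a.total,
        })
    return rows
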