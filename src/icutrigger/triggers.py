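"""Adapted Global Trigger Tool engine: scan ICU records for trigger events.

The default catalog packages the 28-trigger adaptation for adult ICUs —
21 medication-module triggers (abnormal coagulation and glucose values,
antidote/rescue-drug administrations, over-sedation/hypotension, abrupt
medication stop), 3 care-module triggers (a 25% drop in hemoglobin or
hematocrit, patient fall, skin rash) and a laboratory-results module
(sodium < 135 mEq/L, potassium < 3.0 / > 5.5 mmol/L, platelets < 50,000/µL).

Conventions:

* every threshold is strict — a value exactly at the threshold never fires;
* hits are deduplicated to one per trigger per calendar day, except note
  events, which are distinct documented occurrences;
* relative-change rules fire once per excursion episode (reset on recovery),
  with a running-maximum baseline for drops and the admission (first) value
  as baseline for fold-rises.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta
from enum import Enum
from pathlib import Path

import yaml

from ._assets import load_asset
from .model import Analyte, LabResult, NoteKind, PatientRecord, hospital_day

__all__ = [
    "TriggerModule", "RuleKind", "TriggerDef", "TriggerHit",
    "default_catalog", "load_catalog", "scan_record", "scan_cohort",
    "rule_lab_threshold", "rule_relative_change", "rule_med_administered",
    "rule_abrupt_stop", "rule_vital_threshold", "rule_note_event",
    "hits_frame",
]

SEDATIVES = {"midazolam", "fentanyl", "morphine", "propofol", "dexmedetomidine", "ketamine"}


class TriggerModule(str, Enum):
    MEDICATION = "MEDICATION"
    CARE = "CARE"
    LAB = "LAB"


class RuleKind(str, Enum):
    LAB_THRESHOLD = "LAB_THRESHOLD"
    RELATIVE_CHANGE = "RELATIVE_CHANGE"
    MED_ADMINISTERED = "MED_ADMINISTERED"
    ABRUPT_STOP = "ABRUPT_STOP"
    NOTE_EVENT = "NOTE_EVENT"
    VITAL_THRESHOLD = "VITAL_THRESHOLD"


@dataclass(frozen=True)
class TriggerDef:
    trigger_id: str
    name: str
    module: TriggerModule
    rule_kind: RuleKind
    params: dict

    def __post_init__(self):
        required = {
            RuleKind.LAB_THRESHOLD: {"analyte", "direction", "threshold"},
            RuleKind.VITAL_THRESHOLD: {"analyte", "direction", "threshold"},
            RuleKind.RELATIVE_CHANGE: {"analytes", "mode", "magnitude"},
            RuleKind.MED_ADMINISTERED: {"drugs"},
            RuleKind.ABRUPT_STOP: set(),
            RuleKind.NOTE_EVENT: {"kind"},
        }[self.rule_kind]
        missing = required - set(self.params)
        if missing:
            raise ValueError(f"trigger {self.trigger_id}: missing params {sorted(missing)}")


@dataclass(frozen=True)
class TriggerHit:
    patient_id: str
    trigger_id: str
    timestamp: datetime
    hospital_day: int
    evidence: str


def _parse_catalog(raw: dict) -> list[TriggerDef]:
    defs = [
        TriggerDef(t["id"], t.get("name", t["id"]), TriggerModule(t["module"]),
                   RuleKind(t["rule"]), t.get("params", {}) or {})
        for t in raw["triggers"]
    ]
    ids = [d.trigger_id for d in defs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate trigger ids in catalog")
    return defs


def default_catalog() -> list[TriggerDef]:
    """The packaged 28-trigger adapted GTT catalog."""
    return _parse_catalog(load_asset("trigger_catalog.yaml"))


def load_catalog(path: str | Path) -> list[TriggerDef]:
    """Load a user-edited catalog override from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        return _parse_catalog(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# rule evaluators


def _daily_first(qualifying: list[LabResult]) -> list[LabResult]:
    seen: dict[date, LabResult] = {}
    for lab in sorted(qualifying, key=lambda l: l.timestamp):
        day = lab.timestamp.date()
        if day not in seen:
            seen[day] = lab
    return list(seen.values())


def rule_lab_threshold(record: PatientRecord, trigger_id: str, analyte: Analyte,
                       direction: str, threshold: float) -> list[TriggerHit]:
    """One hit per calendar day with at least one value strictly beyond the
    threshold; evidence is the first qualifying value of that day."""
    series = record.sorted_labs(analyte)
    if direction == "LT":
        qualifying = [l for l in series if l.value < threshold]
    elif direction == "GT":
        qualifying = [l for l in series if l.value > threshold]
    else:
        raise ValueError(f"direction must be LT or GT, got {direction!r}")
    return [
        TriggerHit(record.patient_id, trigger_id, lab.timestamp,
                   hospital_day(record, lab.timestamp),
                   f"{analyte.value}={lab.value:g}")
        for lab in _daily_first(qualifying)
    ]


def rule_relative_change(record: PatientRecord, trigger_id: str, analytes: list[Analyte],
                         mode: str, magnitude: float) -> list[TriggerHit]:
    """Episode-based relative-change rule.

    ``DROP_PCT``: fires when a value falls to ``(1 - magnitude)`` of the
    running maximum of prior values; the episode resets once a value recovers
    above that bound. ``RISE_FOLD``: fires when a value reaches ``magnitude``
    times the admission (first) value; resets on recovery below the bound.
    Fewer than two measurements never fire.
    """
    hits = []
    for analyte in analytes:
        series = record.sorted_labs(analyte)
        if len(series) < 2:
            continue
        in_episode = False
        if mode == "DROP_PCT":
            baseline = series[0].value
            for lab in series[1:]:
                bound = (1.0 - magnitude) * baseline
                if lab.value <= bound:
                    if not in_episode:
                        hits.append(TriggerHit(
                            record.patient_id, trigger_id, lab.timestamp,
                            hospital_day(record, lab.timestamp),
                            f"{analyte.value}={lab.value:g} <= {bound:g} (baseline {baseline:g})"))
                        in_episode = True
                else:
                    in_episode = False
                    baseline = max(baseline, lab.value)
        elif mode == "RISE_FOLD":
            baseline = series[0].value
            if baseline <= 0:
                continue
            for lab in series[1:]:
                bound = magnitude * baseline
                if lab.value >= bound:
                    if not in_episode:
                        hits.append(TriggerHit(
                            record.patient_id, trigger_id, lab.timestamp,
                            hospital_day(record, lab.timestamp),
                            f"{analyte.value}={lab.value:g} >= {bound:g} (baseline {baseline:g})"))
                        in_episode = True
                else:
                    in_episode = False
        else:
            raise ValueError(f"mode must be DROP_PCT or RISE_FOLD, got {mode!r}")
    return hits


def rule_med_administered(record: PatientRecord, trigger_id: str,
                          drug_names: list[str]) -> list[TriggerHit]:
    """One hit per calendar day on which a listed drug was administered;
    name matching is case-insensitive against the packaged synonym list."""
    wanted = {d.lower() for d in drug_names}
    by_day: dict[date, tuple[datetime, str]] = {}
    for course in record.medications:
        if course.drug_name.lower() not in wanted:
            continue
        for ts in course.administrations:
            day = ts.date()
            if day not in by_day or ts < by_day[day][0]:
                by_day[day] = (ts, course.drug_name)
    return [
        TriggerHit(record.patient_id, trigger_id, ts, hospital_day(record, ts),
                   f"administration of {name}")
        for ts, name in by_day.values()
    ]


def rule_abrupt_stop(record: PatientRecord, trigger_id: str) -> list[TriggerHit]:
    """A scheduled course stopped before its intended end and before the
    discharge day, with no administration of the drug in the following 24 h.

    Courses without intended-end metadata never fire (narrowest auditable
    definition); a stop on the discharge day is treated as censoring, not an
    abrupt stop.
    """
    hits = []
    for course in record.medications:
        if not course.scheduled or course.stop_time is None or course.intended_end_time is None:
            continue
        if course.stop_time >= course.intended_end_time:
            continue
        if hospital_day(record, course.stop_time) >= hospital_day(record, record.discharge_time):
            continue
        window_end = course.stop_time + timedelta(hours=24)
        drug = course.drug_name.lower()
        readministered = any(
            ts > course.stop_time and ts <= window_end
            for other in record.medications if other.drug_name.lower() == drug
            for ts in other.administrations
        )
        if readministered:
            continue
        hits.append(TriggerHit(
            record.patient_id, trigger_id, course.stop_time,
            hospital_day(record, course.stop_time),
            f"{course.drug_name} stopped {course.stop_time.date()}, "
            f"intended through {course.intended_end_time.date()}"))
    return hits


def rule_vital_threshold(record: PatientRecord, trigger_id: str, analyte: Analyte,
                         direction: str, threshold: float) -> list[TriggerHit]:
    """MAP-style vital threshold: fires on the value alone (daily dedup);
    whether a sedative/opioid course was active is recorded in the evidence."""
    hits = rule_lab_threshold(record, trigger_id, analyte, direction, threshold)
    flagged = []
    for hit in hits:
        active = any(
            c.drug_name.lower() in SEDATIVES
            and c.start_time <= hit.timestamp <= (c.stop_time or record.discharge_time)
            for c in record.medications
        )
        flagged.append(TriggerHit(hit.patient_id, hit.trigger_id, hit.timestamp,
                                  hit.hospital_day,
                                  hit.evidence + ("; sedative active" if active else "")))
    return flagged


def rule_note_event(record: PatientRecord, trigger_id: str, kind: NoteKind) -> list[TriggerHit]:
    """One hit per matching structured note event (no daily dedup: each is a
    distinct documented occurrence)."""
    return [
        TriggerHit(record.patient_id, trigger_id, note.timestamp,
                   hospital_day(record, note.timestamp),
                   f"note {kind.value}: {note.text}" if note.text else f"note {kind.value}")
        for note in record.notes if note.kind is kind
    ]


# ---------------------------------------------------------------------------
# scanning


def _evaluate(record: PatientRecord, tdef: TriggerDef) -> list[TriggerHit]:
    p = tdef.params
    if tdef.rule_kind is RuleKind.LAB_THRESHOLD:
        return rule_lab_threshold(record, tdef.trigger_id, Analyte(p["analyte"]),
                                  p["direction"], float(p["threshold"]))
    if tdef.rule_kind is RuleKind.VITAL_THRESHOLD:
        return rule_vital_threshold(record, tdef.trigger_id, Analyte(p["analyte"]),
                                    p["direction"], float(p["threshold"]))
    if tdef.rule_kind is RuleKind.RELATIVE_CHANGE:
        return rule_relative_change(record, tdef.trigger_id,
                                    [Analyte(a) for a in p["analytes"]],
                                    p["mode"], float(p["magnitude"]))
    if tdef.rule_kind is RuleKind.MED_ADMINISTERED:
        return rule_med_administered(record, tdef.trigger_id, list(p["drugs"]))
    if tdef.rule_kind is RuleKind.ABRUPT_STOP:
        return rule_abrupt_stop(record, tdef.trigger_id)
    if tdef.rule_kind is RuleKind.NOTE_EVENT:
        return rule_note_event(record, tdef.trigger_id, NoteKind(p["kind"]))
    raise ValueError(f"unknown rule kind {tdef.rule_kind}")


def scan_record(record: PatientRecord, catalog: list[TriggerDef] | None = None) -> list[TriggerHit]:
    """Evaluate every catalog rule against one record.

    Returns the union of per-rule hits, deduplicated to one hit per
    (trigger, calendar day) — note-event triggers exempt — sorted by
    timestamp (catalog order breaks ties).
    """
    catalog = default_catalog() if catalog is None else catalog
    hits: list[TriggerHit] = []
    for tdef in catalog:
        rule_hits = _evaluate(record, tdef)
        if tdef.rule_kind is not RuleKind.NOTE_EVENT:
            seen: dict[date, TriggerHit] = {}
            for hit in sorted(rule_hits, key=lambda h: h.timestamp):
                day = hit.timestamp.date()
                if day not in seen:
                    seen[day] = hit
            rule_hits = list(seen.values())
        hits.extend(rule_hits)
    order = {t.trigger_id: i for i, t in enumerate(catalog)}
    hits.sort(key=lambda h: (h.timestamp, order[h.trigger_id]))
    return hits


def scan_cohort(records, catalog: list[TriggerDef] | None = None) -> list[TriggerHit]:
    catalog = default_catalog() if catalog is None else catalog
    out = []
    for rec in records:
        out.extend(scan_record(rec, catalog))
    return out


def hits_frame(hits: list[TriggerHit]):
    """Hits as rows for the CSV export
    (patient_id,trigger_id,timestamp,hospital_day,evidence)."""
    return [
        {"patient_id": h.patient_id, "trigger_id": h.trigger_id,
         "timestamp": h.timestamp.isoformat(), "hospital_day": h.hospital_day,
         "evidence": h.evidence}
        for h in hits
    ]
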