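"""ADR adjudication: causality, severity, mechanism, ATC coding and review merge.

Causality uses the Naranjo probability scale (10 weighted questions; packaged
point table) with the standard score bands — definite >= 9, probable 5-8,
possible 1-4, doubtful <= 0 — and, in parallel, the WHO-UMC categorical
scheme as a packaged, ordered decision table over structured facts.
Severity follows the three-level WHO wording (mild / moderate / severe)
operationalized through three boolean facts, and mechanism follows Rawlins &
Thompson (type A iff dose-dependent and pharmacologically predictable).

Two adjudication paths exist:

* the *review* path — two human reviewer decisions merged field-wise, with a
  third reviewer breaking divergences (:func:`merge_reviews`);
* the *machine-assessed* path — :func:`adjudicate_record` fills the facts
  deterministically from record context (documented reaction notes, active
  suspected-drug courses from the packaged drug-reaction knowledge base,
  dechallenge from course stops, objective evidence from matched laboratory
  trigger hits). Machine output is flagged ``assessed_by="machine"``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, fields
from enum import Enum

from ._assets import load_asset
from .model import NoteKind, PatientRecord, hospital_day
from .triggers import RuleKind, TriggerDef, TriggerHit, default_catalog

logger = logging.getLogger(__name__)

__all__ = [
    "Response", "NaranjoCategory", "WhoCausality", "Severity", "Mechanism",
    "Detection", "NaranjoAnswers", "ADRRecord", "ReviewDecision",
    "naranjo_score", "naranjo_category", "who_causality",
    "classify_severity", "classify_mechanism", "merge_reviews", "atc_lookup",
    "knowledge_base", "machine_answers", "adjudicate_record", "adjudicate_cohort",
    "adrs_frame",
]

YES, NO, UNKNOWN = "yes", "no", "unknown"
Response = str  # one of yes / no / unknown

OBJECTIVE_RULE_KINDS = {RuleKind.LAB_THRESHOLD, RuleKind.VITAL_THRESHOLD, RuleKind.RELATIVE_CHANGE}


class NaranjoCategory(str, Enum):
    DOUBTFUL = "doubtful"
    POSSIBLE = "possible"
    PROBABLE = "probable"
    DEFINITE = "definite"


class WhoCausality(str, Enum):
    CERTAIN = "certain"
    PROBABLE = "probable"
    POSSIBLE = "possible"
    UNLIKELY = "unlikely"
    CONDITIONAL_UNCLASSIFIED = "conditional_unclassified"
    UNASSESSABLE_UNCLASSIFIABLE = "unassessable_unclassifiable"


class Severity(str, Enum):
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


class Mechanism(str, Enum):
    A = "A"
    B = "B"


@dataclass(frozen=True)
class Detection:
    """How an ADR was found: a specific trigger, non-trigger chart review,
    or the spontaneous-report log."""
    source: str  # TRIGGER | NON_TRIGGER_REVIEW | SPONTANEOUS
    trigger_id: str | None = None

    @staticmethod
    def trigger(trigger_id: str) -> "Detection":
        return Detection("TRIGGER", trigger_id)

    @staticmethod
    def non_trigger() -> "Detection":
        return Detection("NON_TRIGGER_REVIEW")


@dataclass(frozen=True)
class NaranjoAnswers:
    answers: tuple[Response, ...]

    def __post_init__(self):
        if len(self.answers) != 10:
            raise ValueError(f"Naranjo requires exactly 10 answers, got {len(self.answers)}")
        bad = [a for a in self.answers if a not in (YES, NO, UNKNOWN)]
        if bad:
            raise ValueError(f"invalid responses: {bad}")


@dataclass(frozen=True)
class ADRRecord:
    patient_id: str
    drug_name: str
    atc_code: str
    reaction: str
    onset_day: int
    detection: Detection
    severity: Severity
    mechanism: Mechanism
    naranjo_score: int
    naranjo_category: NaranjoCategory
    who_causality: WhoCausality
    assessed_by: str = "reviewer"

    def __post_init__(self):
        if naranjo_category(self.naranjo_score) is not self.naranjo_category:
            raise ValueError(
                f"naranjo_category {self.naranjo_category.value} inconsistent with "
                f"score {self.naranjo_score}")


@dataclass(frozen=True)
class ReviewDecision:
    reviewer_id: str
    record: ADRRecord

    def key(self) -> tuple[str, str, str, int]:
        r = self.record
        return (r.patient_id, r.drug_name, r.reaction, r.onset_day)


# ---------------------------------------------------------------------------
# classification primitives


def naranjo_score(answers: NaranjoAnswers) -> int:
    """Sum of per-question points from the packaged Naranjo point table."""
    table = load_asset("naranjo_points.yaml")["questions"]
    total = 0
    for q, ans in zip(table, answers.answers):
        # YAML 1.1 parses bare yes/no keys as booleans
        key = {YES: True, NO: False, UNKNOWN: "unknown"}[ans]
        total += int(q[key])
    return total


def naranjo_category(score: int) -> NaranjoCategory:
    bands = load_asset("naranjo_points.yaml")["bands"]
    if score >= bands["definite_min"]:
        return NaranjoCategory.DEFINITE
    if score >= bands["probable_min"]:
        return NaranjoCategory.PROBABLE
    if score >= bands["possible_min"]:
        return NaranjoCategory.POSSIBLE
    return NaranjoCategory.DOUBTFUL


def who_causality(temporal_plausibility: Response = UNKNOWN,
                  alternative_causes: str = "unknown",
                  dechallenge: str = "unknown",
                  rechallenge: str = "none",
                  data_sufficient: bool = True) -> WhoCausality:
    """WHO-UMC causality from structured facts via the packaged decision table.

    ``alternative_causes`` in {present, excluded, unknown}; ``dechallenge`` /
    ``rechallenge`` in {positive, none, unknown}. A positive rechallenge with
    insufficient data is contradictory and fatal.
    """
    if rechallenge == "positive" and not data_sufficient:
        raise ValueError("contradictory facts: positive rechallenge with insufficient data")
    facts = {
        "temporal_plausibility": temporal_plausibility,
        "alternative_causes": alternative_causes,
        "dechallenge": dechallenge,
        "rechallenge": rechallenge,
        "data_sufficient": "true" if data_sufficient else "false",
    }
    for rule in load_asset("who_umc_table.yaml")["rules"]:
        when = {k: str(v) for k, v in rule["when"].items()}
        if all(facts[k] == v for k, v in when.items()):
            return WhoCausality(rule["category"])
    raise ValueError(f"WHO-UMC decision table does not cover facts {facts}")


def classify_severity(intervention_required: bool, therapy_change: bool,
                      life_threatening_or_prolonging: bool) -> Severity:
    """WHO three-level severity: severe if life-threatening or causing/
    prolonging hospitalization; moderate if treatment or a therapy change was
    required; otherwise mild."""
    if life_threatening_or_prolonging:
        return Severity.SEVERE
    if intervention_required or therapy_change:
        return Severity.MODERATE
    return Severity.MILD


def classify_mechanism(dose_dependent: bool, pharmacologically_predictable: bool) -> Mechanism:
    """Rawlins-Thompson: type A iff dose-dependent AND predictable from the
    drug's pharmacology; anything else is type B."""
    return Mechanism.A if (dose_dependent and pharmacologically_predictable) else Mechanism.B


def merge_reviews(a: ReviewDecision, b: ReviewDecision,
                  tiebreak: ReviewDecision | None = None) -> ADRRecord:
    """Merge two reviewer decisions field-wise; a third review resolves
    divergences. Divergence without a third review is fatal and names the
    divergent fields."""
    if a.key() != b.key():
        raise ValueError(f"reviews concern different ADRs: {a.key()} vs {b.key()}")
    divergent = []
    merged = {}
    for f in fields(ADRRecord):
        va, vb = getattr(a.record, f.name), getattr(b.record, f.name)
        if va == vb:
            merged[f.name] = va
        else:
            divergent.append(f.name)
            if tiebreak is not None:
                merged[f.name] = getattr(tiebreak.record, f.name)
    if divergent and tiebreak is None:
        raise ValueError(f"reviewers diverge on {divergent} and no third review was provided")
    return ADRRecord(**merged)


def atc_lookup(drug_name: str) -> str:
    """ATC code from the packaged mini-dictionary; unmatched names return an
    empty code with a warning."""
    codes = load_asset("atc_codes.yaml")["codes"]
    code = codes.get(drug_name.strip().lower())
    if code is None:
        warnings.warn(f"no ATC code for drug {drug_name!r}", stacklevel=2)
        return ""
    return code


# ---------------------------------------------------------------------------
# machine-assessed adjudication


@dataclass(frozen=True)
class KBEntry:
    drug: str
    reaction: str
    weight: int
    signature_trigger: str | None
    note_kind: NoteKind
    dechallenge: bool
    severity_facts: dict
    mechanism: dict


def knowledge_base() -> list[KBEntry]:
    """The packaged drug-reaction knowledge base."""
    return [
        KBEntry(p["drug"], p["reaction"], int(p["weight"]), p["signature_trigger"],
                NoteKind(p["note_kind"]), bool(p["dechallenge"]),
                p["severity_facts"], p["mechanism"])
        for p in load_asset("adr_knowledge.yaml")["pairs"]
    ]


def machine_answers(dechallenge: bool, objective: bool, alternative: bool) -> NaranjoAnswers:
    """Deterministic Naranjo answers from machine-derivable facts.

    Q1 (previous conclusive reports) is yes for every knowledge-base pair;
    Q2 (event after the drug) is yes by construction of the candidate search;
    Q3 reflects dechallenge, Q5 the presence of an alternative suspected
    drug, Q10 objective (laboratory) confirmation. The remaining questions
    are unanswerable from a retrospective chart and stay unknown.
    """
    a = [UNKNOWN] * 10
    a[0] = YES
    a[1] = YES
    a[2] = YES if dechallenge else UNKNOWN
    a[4] = YES if alternative else UNKNOWN
    a[9] = YES if objective else UNKNOWN
    return NaranjoAnswers(tuple(a))


def _documented_reactions(record: PatientRecord, kb: list[KBEntry]):
    """Reaction-documentation notes: SKIN_RASH notes and OTHER notes whose
    text names a knowledge-base reaction."""
    names = {e.reaction.lower() for e in kb}
    found = []
    for note in record.notes:
        if note.kind is NoteKind.SKIN_RASH:
            found.append((note, "skin rash"))
        elif note.kind is NoteKind.OTHER and note.text.strip().lower() in names:
            found.append((note, note.text.strip().lower()))
    return found


def adjudicate_record(record: PatientRecord, hits: list[TriggerHit],
                      catalog: list[TriggerDef] | None = None,
                      kb: list[KBEntry] | None = None) -> list[ADRRecord]:
    """Machine-assessed adjudication of one record.

    Each documented reaction note anchors a candidate ADR; the suspected drug
    is the knowledge-base-associated course active on the onset day (the most
    recently started when several match). Detection is the closest hit within
    one day whose trigger is a known signature for the drug-reaction pair,
    else non-trigger review. Naranjo/WHO-UMC facts are derived from course
    stops (dechallenge), co-active alternative drugs, and the matched
    evidence kind.
    """
    catalog = default_catalog() if catalog is None else catalog
    kb = knowledge_base() if kb is None else kb
    cat_by_id = {t.trigger_id: t for t in catalog}
    cat_order = {t.trigger_id: i for i, t in enumerate(catalog)}
    by_reaction: dict[str, list[KBEntry]] = {}
    for e in kb:
        by_reaction.setdefault(e.reaction.lower(), []).append(e)

    adrs = []
    for note, reaction_name in _documented_reactions(record, kb):
        onset_day = hospital_day(record, note.timestamp)
        entries = by_reaction.get(reaction_name, [])
        # only scheduled courses can be suspects: as-needed rescue drugs
        # (antiemetics, antihistamines, antidotes) are treatment, not cause
        candidates = []
        for entry in entries:
            for course in record.medications:
                if (course.scheduled and course.drug_name.lower() == entry.drug
                        and course.active_on_day(record, onset_day)):
                    candidates.append((entry, course))
        if not candidates:
            logger.info("patient %s: documented %r on day %d with no associated drug active",
                        record.patient_id, reaction_name, onset_day)
            continue
        # most recently started associated course is the suspected drug
        candidates.sort(key=lambda ec: ec[1].start_time, reverse=True)
        entry, course = candidates[0]

        signature_ids = {e.signature_trigger for e in entries
                         if e.drug == entry.drug and e.signature_trigger}
        matched = [h for h in hits
                   if h.patient_id == record.patient_id and h.trigger_id in signature_ids
                   and abs(h.hospital_day - onset_day) <= 1]
        matched.sort(key=lambda h: (abs(h.hospital_day - onset_day), cat_order[h.trigger_id]))
        if matched:
            detection = Detection.trigger(matched[0].trigger_id)
            objective = cat_by_id[matched[0].trigger_id].rule_kind in OBJECTIVE_RULE_KINDS
        else:
            detection = Detection.non_trigger()
            objective = False

        stop = course.stop_time
        dechallenge = (stop is not None
                       and 0 <= hospital_day(record, stop) - onset_day <= 3
                       and stop < record.discharge_time)
        alternative = any(
            e.drug != entry.drug and c.scheduled and c.drug_name.lower() == e.drug
            and c.active_on_day(record, onset_day)
            for e in entries for c in record.medications
        )
        answers = machine_answers(dechallenge, objective, alternative)
        score = naranjo_score(answers)
        who = who_causality(
            temporal_plausibility=YES,
            alternative_causes="present" if alternative else "unknown",
            dechallenge="positive" if dechallenge else "none",
            rechallenge="none",
            data_sufficient=True,
        )
        adrs.append(ADRRecord(
            patient_id=record.patient_id,
            drug_name=entry.drug,
            atc_code=atc_lookup(entry.drug),
            reaction=entry.reaction,
            onset_day=onset_day,
            detection=detection,
            severity=classify_severity(**entry.severity_facts),
            mechanism=classify_mechanism(**entry.mechanism),
            naranjo_score=score,
            naranjo_category=naranjo_category(score),
            who_causality=who,
            assessed_by="machine",
        ))
    return adrs


def adjudicate_cohort(records, hits: list[TriggerHit],
                      catalog: list[TriggerDef] | None = None,
                      kb: list[KBEntry] | None = None) -> list[ADRRecord]:
    catalog = default_catalog() if catalog is None else catalog
    kb = knowledge_base() if kb is None else kb
    by_patient: dict[str, list[TriggerHit]] = {}
    for h in hits:
        by_patient.setdefault(h.patient_id, []).append(h)
    out = []
    for rec in records:
        out.extend(adjudicate_record(rec, by_patient.get(rec.patient_id, []), catalog, kb))
    return out


def adrs_frame(adrs: list[ADRRecord]):
    """ADRs as rows for the CSV export."""
    return [
        {"patient_id": a.patient_id, "drug_name": a.drug_name, "atc_code": a.atc_code,
         "reaction": a.reaction, "onset_day": a.onset_day,
         "detection": a.detection.source, "trigger_id": a.detection.trigger_id or "",
         "severity": a.severity.value, "mechanism": a.mechanism.value,
         "naranjo_score": a.naranjo_score, "naranjo_category": a.naranjo_category.value,
         "who_causality": a.who_causality.value, "assessed_by": a.assessed_by}
        for a in adrs
    ]
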