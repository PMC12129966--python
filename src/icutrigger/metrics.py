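"""Surveillance statistics: trigger performance, prevalence, detection
breakdown, temporal quartiles, and the underreporting rate.

Trigger performance follows the standard trigger-tool definitions:

* triggers per 100 records  = 100 x (hit count) / n_records
* ADRs per 100 records      = 100 x (ADRs identified by the trigger) / n_records
* PPV (%)                   = 100 x (ADRs identified) / (hit count)

All rates are computed from integer counts and rounded to one decimal only
for display, so the PPV equals the ratio of the *unrounded* rates (rounding
the rates first and dividing would compound rounding error).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .adjudication import ADRRecord
from .model import Cohort, SpontaneousReport
from .triggers import TriggerDef, TriggerHit

__all__ = [
    "TriggerPerformance", "SurveillanceReport",
    "triggers_per_100", "adrs_per_100", "ppv", "performance_table",
    "prevalence", "detection_breakdown", "temporal_quartile",
    "underreporting_rate", "build_report",
]


@dataclass(frozen=True)
class TriggerPerformance:
    trigger_id: str
    hit_count: int
    adr_count: int
    triggers_per_100: float
    adrs_per_100: float
    ppv_pct: float

    def __post_init__(self):
        if self.hit_count == 0 and self.adr_count != 0:
            raise ValueError(f"{self.trigger_id}: ADRs without hits")


@dataclass
class SurveillanceReport:
    n_records: int
    prevalence_pct: float
    total_adrs: int
    adrs_by_detection: dict
    mean_triggers_per_record: float
    performance: list[TriggerPerformance]
    quartile_distribution: dict
    underreporting_pct: float | None


def _rate_per_100(count: int, n_records: int) -> float:
    if n_records <= 0:
        raise ValueError("n_records must be positive")
    return 100.0 * count / n_records


def triggers_per_100(hits: list[TriggerHit], trigger_id: str, n_records: int) -> float:
    return _rate_per_100(sum(h.trigger_id == trigger_id for h in hits), n_records)


def adrs_per_100(adrs: list[ADRRecord], trigger_id: str, n_records: int) -> float:
    n = sum(a.detection.source == "TRIGGER" and a.detection.trigger_id == trigger_id
            for a in adrs)
    return _rate_per_100(n, n_records)


def ppv(hit_count: int, adr_count: int) -> float:
    """PPV in percent from raw counts; 0.0 for zero-hit triggers (the
    convention for antidote triggers that never fired)."""
    if hit_count == 0:
        return 0.0
    return 100.0 * adr_count / hit_count


def performance_table(hits: list[TriggerHit], adrs: list[ADRRecord],
                      catalog: list[TriggerDef], n_records: int) -> list[TriggerPerformance]:
    """Per-trigger performance for every catalog trigger, sorted by PPV then
    hit rate (descending), mirroring the usual presentation."""
    perf = []
    for t in catalog:
        h = sum(x.trigger_id == t.trigger_id for x in hits)
        a = sum(x.detection.source == "TRIGGER" and x.detection.trigger_id == t.trigger_id
                for x in adrs)
        perf.append(TriggerPerformance(
            trigger_id=t.trigger_id, hit_count=h, adr_count=a,
            triggers_per_100=_rate_per_100(h, n_records),
            adrs_per_100=_rate_per_100(a, n_records),
            ppv_pct=ppv(h, a),
        ))
    perf.sort(key=lambda p: (-p.ppv_pct, -p.triggers_per_100, p.trigger_id))
    return perf


def prevalence(adrs: list[ADRRecord], n_records: int) -> float:
    """Percent of patients with at least one ADR (counts patients, not ADRs)."""
    if n_records <= 0:
        raise ValueError("n_records must be positive")
    return 100.0 * len({a.patient_id for a in adrs}) / n_records


def detection_breakdown(adrs: list[ADRRecord]) -> dict[str, float]:
    """Percent of ADRs found by triggers vs non-trigger review; empty for
    zero ADRs."""
    if not adrs:
        return {}
    n = len(adrs)
    trig = sum(a.detection.source == "TRIGGER" for a in adrs)
    return {
        "trigger_detected_pct": 100.0 * trig / n,
        "non_trigger_pct": 100.0 * (n - trig) / n,
    }


def temporal_quartile(onset_day: int, los_days: int) -> int:
    """Quartile of the stay (1-4) in which an ADR occurred:
    ceil(4 * onset_day / los_days), clamped to [1, 4]."""
    if not (1 <= onset_day <= los_days):
        raise ValueError(f"onset day {onset_day} outside stay of {los_days} days")
    return min(4, max(1, math.ceil(4 * onset_day / los_days)))


def quartile_distribution(adrs: list[ADRRecord], los_by_patient: dict[str, int]) -> dict[int, int]:
    """Count of ADRs per stay quartile."""
    dist = {1: 0, 2: 0, 3: 0, 4: 0}
    for a in adrs:
        dist[temporal_quartile(a.onset_day, los_by_patient[a.patient_id])] += 1
    return dist


def _norm(name: str) -> str:
    return name.strip().lower()


def underreporting_rate(adrs: list[ADRRecord],
                        reports: list[SpontaneousReport]) -> float | None:
    """Percent of ADRs with no matching spontaneous report (matched on
    patient and synonym-normalized drug). ``None`` (not applicable) when
    there are no ADRs."""
    if not adrs:
        return None
    reported = {(r.patient_id, _norm(r.drug_name)) for r in reports}
    unmatched = sum((a.patient_id, _norm(a.drug_name)) not in reported for a in adrs)
    return 100.0 * unmatched / len(adrs)


def build_report(cohort: Cohort, hits: list[TriggerHit], adrs: list[ADRRecord],
                 catalog: list[TriggerDef]) -> SurveillanceReport:
    """Assemble the full surveillance report for a scanned, adjudicated cohort."""
    from .model import los_whole_days

    n = cohort.n_records
    los_by_patient = {r.patient_id: los_whole_days(r) for r in cohort.records}
    by_detection: dict[str, int] = {}
    for a in adrs:
        by_detection[a.detection.source] = by_detection.get(a.detection.source, 0) + 1
    return SurveillanceReport(
        n_records=n,
        prevalence_pct=prevalence(adrs, n) if n else 0.0,
        total_adrs=len(adrs),
        adrs_by_detection=by_detection,
        mean_triggers_per_record=(len(hits) / n) if n else 0.0,
        performance=performance_table(hits, adrs, catalog, n) if n else [],
        quartile_distribution=quartile_distribution(adrs, los_by_patient),
        underreporting_pct=underreporting_rate(adrs, cohort.spontaneous_reports),
    )
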