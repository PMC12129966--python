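"""Pipeline orchestration: simulate -> scan -> adjudicate -> report -> stats.

Every stage reads and writes the flat CSV artifacts defined by the
individual modules, so each stage can be re-run from the previous stage's
output. A run manifest (config + seed + version) makes runs auditable;
identical configuration and seed reproduce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .adjudication import ADRRecord, Detection, Mechanism, NaranjoCategory, Severity, \
    WhoCausality, adjudicate_cohort, adrs_frame
from .metrics import SurveillanceReport, build_report
from .model import Cohort, LoadResult, read_cohort, write_cohort
from .stats import compare_groups, stepwise_logistic
from .synth import GeneratorConfig, default_config, generate, ground_truth_frame
from .triggers import TriggerDef, TriggerHit, default_catalog, hits_frame, load_catalog
from datetime import datetime

logger = logging.getLogger(__name__)

__all__ = ["run_simulate", "run_scan", "run_adjudicate", "run_report", "run_stats",
           "run_pipeline", "load_hits", "load_adrs", "cohort_table"]


def _timed(stage: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            logger.info("stage %-12s %6.2f s", stage, time.perf_counter() - self.t0)
            return False
    return _T()


def _write_manifest(out: Path, seed: int | None, extra: dict | None = None):
    manifest = {"tool": "icutrigger", "version": __version__, "seed": seed}
    manifest.update(extra or {})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_simulate(out: Path, config: GeneratorConfig | None = None,
                 seed: int | None = None) -> tuple[Cohort, Path]:
    """Generate a synthetic cohort and write the interchange CSVs plus
    ground_truth.csv."""
    cfg = default_config() if config is None else config
    if seed is not None:
        cfg.seed = seed
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    with _timed("simulate"):
        cohort, truth = generate(cfg)
        write_cohort(cohort, out)
        ground_truth_frame(truth).to_csv(out / "ground_truth.csv", index=False,
                                         lineterminator="\n")
    _write_manifest(out, cfg.seed, {"n_patients": cfg.n_patients})
    logger.info("simulated %d records, %d ground-truth ADRs", cohort.n_records, len(truth.adrs))
    return cohort, out


def run_scan(cohort_dir: Path, out: Path,
             catalog: list[TriggerDef] | None = None) -> list[TriggerHit]:
    """Scan a cohort directory against the trigger catalog; writes hits.csv."""
    from .triggers import scan_cohort

    catalog = default_catalog() if catalog is None else catalog
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    result = read_cohort(cohort_dir)
    _log_load(result)
    with _timed("scan"):
        hits = scan_cohort(result.cohort.records, catalog)
    pd.DataFrame(hits_frame(hits),
                 columns=["patient_id", "trigger_id", "timestamp", "hospital_day",
                          "evidence"]).to_csv(out / "hits.csv", index=False, lineterminator="\n")
    logger.info("scanned %d records: %d hits", result.cohort.n_records, len(hits))
    return hits


def run_adjudicate(cohort_dir: Path, hits_csv: Path, out: Path,
                   catalog: list[TriggerDef] | None = None) -> list[ADRRecord]:
    """Machine-assessed adjudication; writes adrs.csv."""
    catalog = default_catalog() if catalog is None else catalog
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    result = read_cohort(cohort_dir)
    hits = load_hits(hits_csv)
    with _timed("adjudicate"):
        adrs = adjudicate_cohort(result.cohort.records, hits, catalog)
    pd.DataFrame(adrs_frame(adrs),
                 columns=["patient_id", "drug_name", "atc_code", "reaction", "onset_day",
                          "detection", "trigger_id", "severity", "mechanism",
                          "naranjo_score", "naranjo_category", "who_causality",
                          "assessed_by"]).to_csv(out / "adrs.csv", index=False,
                                                 lineterminator="\n")
    logger.info("adjudicated %d ADRs", len(adrs))
    return adrs


def run_report(cohort_dir: Path, hits_csv: Path, adrs_csv: Path, out: Path,
               catalog: list[TriggerDef] | None = None) -> SurveillanceReport:
    """Surveillance report; writes performance.csv and report.json."""
    catalog = default_catalog() if catalog is None else catalog
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    result = read_cohort(cohort_dir)
    hits = load_hits(hits_csv)
    adrs = load_adrs(adrs_csv)
    with _timed("report"):
        report = build_report(result.cohort, hits, adrs, catalog)
    pd.DataFrame([{
        "trigger_id": p.trigger_id, "hit_count": p.hit_count, "adr_count": p.adr_count,
        "triggers_per_100": round(p.triggers_per_100, 1),
        "adrs_per_100": round(p.adrs_per_100, 1),
        "ppv_pct": round(p.ppv_pct, 1),
    } for p in report.performance]).to_csv(out / "performance.csv", index=False,
                                           lineterminator="\n")
    payload = dataclasses.asdict(report)
    payload["quartile_distribution"] = {str(k): v for k, v in report.quartile_distribution.items()}
    (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return report


def run_stats(cohort_dir: Path, adrs_csv: Path, out: Path) -> dict:
    """Unit comparisons, ADR-strata comparisons, and the stepwise logistic
    risk-factor model; writes stats.json."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    result = read_cohort(cohort_dir)
    adrs = load_adrs(adrs_csv)
    table = cohort_table(result.cohort, adrs)
    payload: dict = {"n_records": len(table), "comparisons": [], "logistic_model": None}
    with _timed("stats"):
        pairs = [] if table.empty else [
            ("male", "c19_icu"), ("age", "c19_icu"), ("los_days", "c19_icu"),
            ("death", "c19_icu"), ("age", "has_adr"), ("los_days", "has_adr"),
            ("male", "has_adr")]
        for variable, grouping in pairs:
            try:
                c = compare_groups(table, variable, grouping)
            except ValueError as exc:
                logger.warning("comparison %s by %s skipped: %s", variable, grouping, exc)
                continue
            payload["comparisons"].append({
                "variable": variable, "grouping": grouping, "test": c.test_used,
                "statistic": c.statistic, "p_value": c.p_value})
        if not table.empty:
            try:
                model = stepwise_logistic(table, "has_adr",
                                          ["age", "male", "los_days", "c19_icu"])
                payload["logistic_model"] = {
                    "selected": [dataclasses.asdict(e) for e in model.selected]}
            except ValueError as exc:
                logger.warning("logistic model skipped: %s", exc)
    (out / "stats.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return payload


def run_pipeline(out: Path, config: GeneratorConfig | None = None,
                 seed: int | None = None, cohort_dir: Path | None = None,
                 catalog_path: Path | None = None) -> SurveillanceReport:
    """End-to-end run: simulate (or read an existing cohort directory), scan,
    adjudicate, report, stats. Returns the surveillance report."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    catalog = load_catalog(catalog_path) if catalog_path else default_catalog()
    if cohort_dir is None:
        _, cohort_dir = run_simulate(out / "cohort", config, seed)
    cohort_dir = Path(cohort_dir)
    run_scan(cohort_dir, out, catalog)
    run_adjudicate(cohort_dir, out / "hits.csv", out, catalog)
    report = run_report(cohort_dir, out / "hits.csv", out / "adrs.csv", out, catalog)
    run_stats(cohort_dir, out / "adrs.csv", out)
    _write_manifest(out, seed if seed is not None else (config.seed if config else None))
    if report.n_records == 0:
        logger.warning("no eligible patients in input; report is empty")
    return report


# ---------------------------------------------------------------------------
# artifact loaders


def _log_load(result: LoadResult):
    for v in result.violations:
        logger.warning("validation: %s line %s: %s", v.file, v.line, v.message)
    for e in result.exclusions:
        logger.info("excluded %s: %s", e.patient_id, e.reason)


def load_hits(path: Path) -> list[TriggerHit]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        TriggerHit(r["patient_id"], r["trigger_id"],
                   datetime.fromisoformat(r["timestamp"]),
                   int(r["hospital_day"]), r["evidence"])
        for _, r in df.iterrows()
    ]


def load_adrs(path: Path) -> list[ADRRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        detection = (Detection.trigger(r["trigger_id"]) if r["detection"] == "TRIGGER"
                     else Detection(r["detection"]))
        out.append(ADRRecord(
            patient_id=r["patient_id"], drug_name=r["drug_name"], atc_code=r["atc_code"],
            reaction=r["reaction"], onset_day=int(r["onset_day"]), detection=detection,
            severity=Severity(r["severity"]), mechanism=Mechanism(r["mechanism"]),
            naranjo_score=int(r["naranjo_score"]),
            naranjo_category=NaranjoCategory(r["naranjo_category"]),
            who_causality=WhoCausality(r["who_causality"]),
            assessed_by=r["assessed_by"]))
    return out


def cohort_table(cohort: Cohort, adrs: list[ADRRecord]) -> pd.DataFrame:
    """Patient-level analysis table for the stats stage."""
    from .model import Outcome, Sex, Unit, los_whole_days

    with_adr = {a.patient_id for a in adrs}
    columns = ["patient_id", "age", "male", "los_days", "c19_icu", "death", "has_adr"]
    if not cohort.records:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame([{
        "patient_id": r.patient_id,
        "age": r.age,
        "male": int(r.sex is Sex.MALE),
        "los_days": los_whole_days(r),
        "c19_icu": int(r.unit is Unit.C19_ICU),
        "death": int(r.outcome is Outcome.DEATH),
        "has_adr": int(r.patient_id in with_adr),
    } for r in cohort.records])
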