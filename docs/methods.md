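# Methods

This note records the modelling choices behind `icutrigger`: what the
pipeline computes, what the synthetic cohort emulates, and where the open
design decisions were settled.

## Data model and eligibility

A cohort is a set of single ICU stays in five flat CSV files (patients,
labs, medications + administrations, notes, spontaneous reports).
Timestamps are ISO-8601; hospital days are 1-based calendar days (the
admission calendar day is day 1), matching the clinical "on the 8th day"
convention. Length of stay is the fractional difference admit→discharge;
whole-day summaries use its ceiling so a 25-hour stay counts as 2 observed
days and is never rounded out of the cohort.

Eligibility mirrors adult-ICU surveillance practice: age > 18 years, stay
longer than 24 h, at least one prescribed medication. Ineligible records
are excluded with a logged reason rather than rejected; malformed rows are
collected as line-referenced violations and never silently dropped.
Multi-admission linkage and stays spanning the study-year boundary are out
of scope (the generator does not produce them).

## Trigger engine

The 28-trigger catalog is a YAML asset, so a deployment can retune
thresholds (e.g. restore PTT > 100 s) without code changes. Numerical
choices:

* **Strict thresholds.** "Greater than 50 s" and "< 50 mg/dL" are read
  literally: a value exactly at the threshold never fires. A property test
  probes every threshold at the boundary.
* **Daily deduplication.** One hit per trigger per calendar day. Rates
  above 100 per 100 records are therefore possible (multiple days per
  stay), but continuous MAP monitoring cannot explode the counts. Note
  events (fall, rash) are distinct documented occurrences and exempt.
* **Relative-change rules** fire once per excursion episode. Drops
  (Hb/Ht ≥ 25%) measure against the running maximum of prior values;
  2× rises (BUN/creatinine) measure against the admission value. An
  episode resets when the series recovers past the bound, so one bleed is
  one hit however many low values it produces.
* **Abrupt stop** is the narrowest auditable definition: a *scheduled*
  course, stopped before its recorded intended end and before the
  discharge calendar day, with no administration of the drug in the
  following 24 h. Courses without intended-end metadata never fire; a stop
  on the discharge day is censoring.
* **Over-sedation/hypotension** fires on MAP < 70 mmHg alone; whether a
  sedative/opioid course was active is recorded in the hit evidence, not
  used as a gate.

## SOFA

Six organ subscores (0–4) from PaO2/FiO2, platelets, bilirubin, MAP, GCS
and creatinine, with the standard published cut-points packaged as an
editable asset. Two documented simplifications: the cardiovascular score
uses MAP plus a vasopressor-support flag (score 2 when support is active;
without dose data scores 3–4 are unreachable), and urine output is ignored
for the renal score. Trajectories are assessed at fixed intervals (default
24 h, configurable to the 48 h charting minimum) with
last-observation-carried-forward; a variable never measured scores 0 with a
logged warning, and the admission assessment may use the first measurement
charted within the first interval (admission labs are drawn at admission
but resulted hours later).

## Adjudication

Naranjo points and score bands, and the WHO-UMC decision table, are config
assets: the pipeline applies published scales and should not hard-code
them. Severity is operationalized through three booleans (intervention
required / therapy change / life-threatening-or-prolonging → mild,
moderate, severe); mechanism through two (type A iff dose-dependent AND
pharmacologically predictable). The WHO-UMC table is ordered from strongest
evidence down, which makes it monotone: adding supporting evidence can only
strengthen the category. A positive rechallenge with insufficient data is
rejected as contradictory.

The human path merges two reviewer decisions field-wise, a third reviewer
resolving divergences; divergence without a third review is an error that
names the fields.

The machine-assessed path (flagged `assessed_by="machine"`) anchors on
documented reaction notes, then:

1. the *suspected drug* is the most recently started **scheduled** course
   of a drug linked to that reaction in the packaged knowledge base
   (as-needed rescue drugs — antiemetics, antihistamines, antidotes — are
   treatment, never suspects);
2. *detection* is the closest hit within one day whose trigger is a known
   signature for the drug–reaction pair, else non-trigger review;
3. Naranjo Q1/Q2 are affirmative by construction of the candidate search,
   Q3 (dechallenge) requires a course stop within 3 days of onset, Q5 an
   alternative associated drug co-active at onset, Q10 objective
   (laboratory/vital) evidence on the matched hit; the remaining questions
   are unanswerable from a retrospective chart and stay unknown.

Severity and mechanism facts come from the knowledge base entry for the
pair. This is deliberate: in a synthetic-validation setting the same
clinical facts must drive both the generator and the adjudicator, so the
recovery tests exercise the *reconstruction path* (raw record → note →
course → hit → classification), not clinical judgement. Passing them shows
the pipeline faithfully recovers what was embedded; it does not show the
knowledge base generalizes to real charts.

## Synthetic cohort

The generator's defaults are the packaged study conditions: 135 patients,
56.3% G-ICU; age 60.5 ± 15.6 (G-ICU) / 62.3 ± 14.5 (C19-ICU) years from
normals truncated to [19, 100]; length of stay 12.2 ± 10.9 / 13.8 ± 11.0
days from moment-matched lognormals truncated above 1 day (whole days,
minimum 2); ICU mortality 69.6% (independent Bernoulli — mortality is not
coupled to severity, a stated non-goal); ADR prevalence 40.7%.

**ADR risk** is patient-level logistic:
logit p = β0 + ln(1.039)·(age−61) + ln(1.100)·(LOS−13) + ln(2.379)·1[C19-ICU],
with β0 root-found per cohort so the covariate-averaged prevalence equals
the configured value exactly in expectation. The unit coefficient is the
"higher template intensity" of the C19 unit, and stepwise logistic
regression on generated cohorts recovers it (mean OR within [2.0, 2.9] at
n = 2000 over 50 replicates; 95% CI coverage within [90%, 99%]).

**ADR counts and templates.** Affected patients draw a truncated geometric
number of ADRs (p = 55/85, max 5 → mean ≈ 1.545; only the totals 85 ADRs /
55 patients are published, so the geometric form is an assumption). Each
ADR samples a drug–reaction template from the knowledge base
(weights sum to 85, dominated by insulin hypoglycemia (22), morphine
constipation (13), heparin-group bleeding (14)), never repeating a
reaction or drug within one patient and never combining cross-associated
pairs (two anticoagulants would make suspected-drug attribution ambiguous
— real chart review faces that ambiguity; the generator deliberately does
not). Because this exclusion shifts realized shares away from raw weights
by up to ~15%, the calibration uses effective shares estimated once by an
internal fixed-seed Monte Carlo. Onset day is Beta(2, 2) over the stay
fraction, concentrating ADRs in the second and third quartiles of the stay.

**Embedding.** Each ADR gets a suspected-drug course overlapping onset, a
documentation note, and its signature event on the onset day: a lab
excursion (glucose 42 mg/dL, K 2.6/6.1 mmol/L, Na 128 mEq/L, platelets
38,000/µL, PTT 68 s, INR 4.4, MAP 62 mmHg, Hb at 68% of baseline,
creatinine at 2.15× admission), a rescue administration, a rash note, or
an early course stop. Dechallenge stops set intended end = stop so they do
not also fire the abrupt-stop trigger; only abrupt-stop-signature
templates stop before their intended end. Twenty of the 85 template
weights carry no signature — those ADRs are reachable only by note review,
giving the ~76.5% trigger-detected share.

**Noise.** Per-trigger background events are Poisson per record (on
distinct days) at rates = target per-100 rate − ADR-linked contribution,
so total hit rates match the packaged surveillance rates in expectation.
The four perfect-PPV triggers (PTT > 50 s, skin rash, protamine,
hydroxyzine) get zero noise by design: their published property is that
every occurrence indicated an ADR. Baseline physiology is generated inside
non-firing ranges (platelets ≥ 50,000/µL, MAP > 70, sodium ≥ 136,
creatinine within 1.1× of admission), so *every* hit is attributable to a
configured channel; SOFA severity comes from bounded per-organ random
walks calibrated so the cohort mean-of-means is ≈ 8.4 (admission ≈ 8.1).

**What the generator does not emulate:** physiological coupling between
labs (severity does not drive mortality or LOS), drug–drug interactions,
free-text notes, COVID-19 disease dynamics, seasonal admission patterns.
Published per-trigger ADR rates and the drug-level ADR counts are mutually
inconsistent at n = 135 (the per-trigger ADR column implies ~95
trigger-identified ADRs, the totals say 65 of 85); the templates follow
the drug-level counts and the 65/20 detected split, so per-trigger ADR
rates are approximated by the template→signature mapping rather than
matched to the decimal. Recovery tests therefore compare pipeline
estimates to the *configuration-implied* expectations, not to the printed
table.

**Spontaneous reports** default to probability 0 per ADR — the study
condition in which none of the observed ADRs had been reported, a 100%
underreporting rate.

## Statistics

Chi-square (no continuity correction) for categorical comparisons,
switching to Fisher's exact test for 2×2 tables when any expected *or
observed* cell is below 5 — the conservative small-sample convention; a
pure expected-count rule would put the canonical 10/10-margin table with
observed cells of 1 (all expected counts exactly 5) under chi-square.
Mann-Whitney U (two-sided; exact for small tie-free samples) for
quantitative comparisons. The risk-factor model is forward stepwise
logistic regression with entry/stay p = 0.05 (the direction and thresholds
are a documented choice — only "stepwise, 5% significance" is specified),
Wald CIs on the OR scale, and explicit errors for separation and collinear
candidates.

## Problem sizes and tolerances

Deterministic arithmetic (rate/PPV reproduction) runs at the published
n = 135. Distributional recovery uses n = 2000 (prevalence, per-trigger
PPV within 3 SE of the configuration-implied values, allowing for Poisson
variation of the ADR numerator), n = 5000 for demographic moment recovery,
and 20–50 replicates of n = 2000 for the odds-ratio and CI-coverage
checks. Scan-versus-rules equivalence is brute-forced on 200 random small
records. These sizes keep the full test suite within a few minutes on one
core while leaving every stochastic band at 3 SE.

## Known limitations

* The knowledge base couples generator and machine adjudicator; recovery
  results validate the pipeline mechanics, not clinical accuracy.
* PPV is the only trigger-performance measure; sensitivity/specificity
  would need a full gold-standard review, which the synthetic ground truth
  could provide but the study design does not define.
* Machine-assessed Naranjo answers can only reach the possible/probable
  bands (retrospective charts cannot answer rechallenge/placebo/toxic-level
  questions), so definite classifications require the human review path.
* The cardiovascular SOFA subscore underestimates vasopressor-dependent
  dysfunction when dose data are absent.
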