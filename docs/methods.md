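# Methods

## The case-finding model

`dmscore` implements a point-based, rule-driven computable phenotype for
diabetes over longitudinal structured EHR data. Each patient is a stream of
dated, setting-tagged events of four kinds: encounter diagnosis codes
(ICD-9-CM), laboratory results (HbA1c, fasting glucose, random glucose,
2-hour OGTT), medication orders (metformin / other diabetes drug / other),
and problem-list or past-medical-history entries. Eight criteria assign
fixed point weights to qualifying evidence (see the README table); the
cumulative total classifies the patient as **none** (0 points), **possible**
(strictly between 0 and 1), or **diabetes** (≥ 1), and the diagnosis date is
the earliest calendar date on which the running total reaches 1.

The weights encode two ideas. First, ADA diagnostic logic: a single
elevated outpatient glucose is half the evidence needed (0.5 points, so two
on distinct days diagnose), while one qualifying HbA1c or one non-metformin
diabetes drug order is sufficient alone (1.0). Second, robustness to known
EHR noise: metformin (also prescribed for pre-diabetes and PCOS),
problem-list entries (often stale), and single encounter codes (often
miscoded) each carry sub-unit weights (0.75, 0.40, 0.75) so that any one of
them alone lands in the "possible" band rather than producing a false
positive — but two such signals, or one plus a lab, still cross the
threshold.

### Accrual policy

The source criteria table is silent on how repeated evidence accrues. We
resolve it per criterion and expose the choice in the configuration:

- **per_distinct_date** (labs, encounter codes): at most one contribution
  per (criterion, calendar date). This makes two dated fasting glucoses sum
  to 1.0 and two dated 250.xx encounters diagnostic (0.75 + 0.75), matching
  the widely used two-code claims standard, while same-day duplicate draws
  or multiple codes on one claim count once — a single visit is single
  evidence. Distinct test kinds on one day each count (fasting glucose +
  HbA1c on the same day can diagnose), since they are independent
  diagnostic observations.
- **once_per_patient** (metformin, other diabetes medication, history
  entries): a single contribution on the first qualifying date. Refills and
  re-listed problems repeat clerically, not clinically; letting two
  metformin refills reach 1.5 points would recreate exactly the false
  positives the sub-unit metformin weight exists to prevent. Problem-list
  and past-medical-history entries are one criterion: a patient with both
  still accrues 0.40 once.

Because contributions are keyed by calendar date and the weights are
per-criterion constants, the result is invariant under permutation of
same-date events (property-tested).

### Setting restrictions

"Outpatient only" criteria (glucoses, medications) exclude both inpatient
*and* emergency/urgent-care events: acute illness produces stress
hyperglycemia and sliding-scale insulin orders in both environments. The
encounter-code and HbA1c criteria accept inpatient and outpatient but not
emergency/urgent settings. All masks are configurable.

### Numerical choices

Point weights are exact decimals (`decimal.Decimal`, hundredths); totals
are exact sums and the threshold comparison is exact — 0.99 is "possible",
1.00 is "diabetes", with no floating-point tolerance. Lab thresholds are
inclusive (≥), including the boundary values 6.5 %, 126 and 200 mg/dL. Lab
units must match the canonical units for the test kind (% for HbA1c, mg/dL
for glucoses); mismatches raise an error rather than being converted.

## Claims comparator

The baseline rule identifies diabetes from two ICD-9 250.xx encounter codes
in any care setting, dated at the second code. Codes are deduplicated to
one per calendar day by default ("two encounters" means separate claims);
the dedup is switchable. Whenever the claims rule fires on a chart whose
diabetes codes are all in settings the point model scores, the point
model's date is never later than the claims date (two codes already reach
the threshold) — a tested invariant.

## Validation statistics

- 3×3 agreement table (model × gold over none/possible/diabetes) with
  Cohen's kappa, unweighted and linear-weighted (disagreement weight
  |i−j|/(k−1) over the ordered categories); on 2×2 tables the two coincide.
  Kappa is reported as undefined (not 0) when chance agreement is 1.
- Sensitivity, specificity, PPV, NPV under both dichotomisations of
  "possible" (folded into negative — the primary analysis — or into
  positive). Zero-denominator metrics are reported as undefined. PPV/NPV
  are prevalence-dependent; the report carries a standing note that
  case-enriched samples inflate them.
- ROC over point thresholds: predict positive iff total ≥ t, by default at
  every observed distinct total; area by the trapezoidal rule over the
  (1−specificity, sensitivity) staircase closed at (0,0) and (1,1). On the
  full sweep this equals the tie-corrected Mann–Whitney probability
  (cross-checked against pairwise counting and scikit-learn's rank-based
  AUC in tests).
- Date agreement: exact matches and matches within a window, default 92
  days — the longest span of three calendar months, chosen over
  calendar-month arithmetic for locale-robustness. Two window modes are
  reported: symmetric (|model − gold| ≤ window) and one-sided
  ("model_late": 0 ≤ model − gold ≤ window, i.e. the model may trail the
  chart but not anticipate it). Signed day delays are retained for
  plotting. We do not attempt a chance-corrected kappa on dates: with a
  single reference date per patient the agree/disagree indicator against a
  perfect reference is degenerate, so the within-window proportion is the
  honest summary.
- No bootstrap or small-sample confidence intervals; point estimates only.

## Synthetic cohort generator

The generator exists so every other module is testable without patient
data. Each synthetic patient is drawn from an archetype whose construction
*implies* its gold label and, for diabetics, a gold diagnosis date equal to
the earliest date the generated chart evidence satisfies the diagnostic
rule:

- `true_diabetic_labs` — two or more qualifying outpatient glucoses on
  distinct dates (gold date = second); no encounter codes, so these
  patients are invisible to the claims comparator by construction.
- `true_diabetic_meds` — one outpatient non-metformin diabetes drug order
  (gold date = order date), optionally followed by later 250.xx coding.
- `true_diabetic_codes` — two or more dated 250.xx encounters (gold date =
  second code date).
- `prediabetic_metformin`, `pcos_metformin` — metformin orders plus
  sub-threshold glycemia; gold "none". Restoring the metformin weight to
  1.0 flips these to false positives (tested), which is the reason the
  shipped weight is 0.75.
- `stale_problem_list` — an isolated 250.00 history entry; gold "none".
- `miscoded_single_icd9` — one isolated 250.xx encounter; gold "none".
  Restoring the encounter weight to 1.0 flips these to false positives.
- `healthy`, `healthy_elderly` — distractor encounters (hypertension,
  pneumonia, etc.) and normal labs; the elderly variant (≥ 55 at cohort
  start) populates the age-restricted negative stratum.

Event counts per patient are Poisson with mean 6.6 filler encounters — a
realistic ambulatory utilisation level over a ~2-year window (the default
window is 2009-01-01 to 2011-04-30). Diabetic lab values are lognormal
(HbA1c centred near 8.1 %, fasting glucose near 155 mg/dL, floored at the
diagnostic cut-offs); non-diabetic values are uniform in normal or
pre-diabetic ranges. These distributions are conveniences chosen to be
clinically plausible, not estimates of any real population, and are
archetype parameters.

One integer seed drives everything; each patient consumes a substream keyed
by (seed, patient index), so cohorts are byte-reproducible and a cohort's
first *n* patients do not change when it grows.

Two sampling utilities mirror chart-review study design: stratified
sampling by model category (e.g. 50/25/25 for derivation-style review,
50/10/40 for validation-style review), without replacement, taking whole
strata with a warning when a quota exceeds the stratum; and an age
restriction that drops patients under 50 (at first encounter) from the
model-negative stratum only, enriching it for plausible false negatives.

### What passing tests do and do not show

On noise-free synthetic cohorts the model attains sensitivity =
specificity = 1.0 with 100 % exact date agreement *by construction* — the
generator plants exactly the evidence the rule reads. This validates the
implementation (accrual, dating, classification), not the clinical accuracy
of the rule: real charts contain coding idiosyncrasies, unit chaos,
cross-system fragmentation and subtype ambiguity the generator deliberately
omits. The noise archetypes probe the *direction* of known failure modes,
not their real-world rates.

## Problem sizes

The default test run uses ≥ 1000 randomized timelines for the brute-force
prefix oracle, a 500-patient noise-free cohort for recovery, 300-patient
mixed cohorts for the recalibration checks, and ≥ 500 random tables/score
sets for metric cross-checks; the whole suite completes in seconds.

## Known limitations

- No distinction of type 1 / type 2 / secondary diabetes.
- No incident-vs-prevalent disambiguation for systems migrating from paper
  records: the first EHR evidence of a long-standing case reads as a new
  diagnosis.
- ICD-9 only; no ICD-10 mapping, HL7/FHIR/OMOP ingestion, or free-text
  parsing.
- PPV/NPV on enriched validation samples are inflated and are not corrected
  to a target prevalence.
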