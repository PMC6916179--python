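# Methods

This note documents the models and procedures implemented in
`rxadhere`, the assumptions behind the synthetic cohort generator, the
parameters that matter, and the numerical choices made where the design
was genuinely open.

## 1. Cohort derivation

Input is four flat tables (patients, prescriptions, clinical events,
observations) with dates as integer day offsets from a fixed study
epoch (nominally 2004.0; ages derive from `birth_year` via
days/365.25). The eligibility cascade removes, in a fixed order with
first-match attribution so the audit log is deterministic and exactly
conserves counts:

1. no diabetes code on record;
2. PCOS treated with metformin;
3. other diabetes aetiology;
4. likely type 1 diabetes: age at diagnosis < 35 years;
5. likely type 1 diabetes: insulin within 1 year of diagnosis;
6. under 1 year of prescribing data (last prescription − registration
   start < 365 days);
7. registration gaps (a boolean supplied by the reader);
8. two distinct oral classes first issued on the same day ("dual
   start" — with date-only data this is the only operationalisation);
9. first glucose-lowering prescription within 91 days of registration
   (possible continuation of prior therapy from an unseen practice);
10. injectable or oral-solution first/second line;
11. no second therapy line.

The diagnosis date is the earliest of: first diabetes code, first
glucose-lowering prescription, first HbA1c at or above the
diabetes-range threshold. The threshold is configuration (default
48 mmol/mol, the conventional diagnostic cut) because no single value
is canonical in routine data.

Therapy lines: the first line is the glucose-lowering class with the
earliest issue date; the second is the first distinct class started
strictly later. A line's end event is classified from its own refill
series: `ongoing_at_1yr` when its prescriptions continue to/past day
365; `switched` when a later class starts in-year after the line's last
prescription; `records_end` when registration ends in-year; otherwise
`stopped_gap`.

## 2. Medical possession ratio

MPR = 100 × supply / denominator, where supply sums quantity/dose over
valid-dose prescriptions issued strictly before the adherence-period
end date and the denominator is the days from the first prescription to
that end date. End-date rules: (i) start + 365 when the line continues
through the year; (ii) otherwise the penultimate prescription on or
before the stop/switch/records-end date — a following prescription is
needed to know the days covered.

Validity and edge handling, in evaluation order:

* a break > 183 days ("6 months") between prescriptions beginning
  inside the first year truncates the episode at the last prescription
  before the break and reclassifies the end as stopping; if fewer than
  two prescriptions remain, the episode is reported as `gap_gt_6mo`;
* at least 3 prescriptions with a recorded dose, issued on or before
  the end date, are required (`all_doses_missing` when none has a dose,
  `too_few_prescriptions` otherwise). Counting is inclusive of an
  end-date prescription while supply is summed strictly before it: the
  end-date prescription witnesses continuation but its supply falls
  outside the window;
* the period must span ≥ 90 days. "Covering at least 90 days" is read
  as calendar span, not summed supply (the alternative reading is noted
  as open); episodes too short because they stopped/switched are
  labelled `stopped_changed_lt_90d`, those cut short by the record
  `span_lt_90d`;
* each missing-dose prescription is dropped from the numerator and the
  interval from it to the next prescription is removed from the
  denominator;
* MPR < 20% or > 120% is treated as a dose-recording error and voided
  (`out_of_range_lt20` / `out_of_range_gt120`); the patient's other
  line remains analysable.

All divisions are exact floating point; MPR is rounded to one decimal
only at output. Non-adherence is MPR ≤ 80% (80.0 itself is
non-adherent; 20.0 is a valid value). For continuous modelling the MPR
is capped at 100%, where its association with the outcome flattens.

The engine is verified, episode by episode, against an independent
day-walk oracle in the test suite: a calendar-day loop with a
medication-stock counter that re-derives the end date, the
missing-dose denominator removal and the possession count one day at a
time, and must agree in status everywhere and within 0.5 percentage
points wherever an MPR is defined.

## 3. Baseline predictors

All features are strictly baseline (a look-ahead-freedom test perturbs
every post-start record and requires identical features). Windows:

* BMI and HbA1c: closest observation at or before the start date
  within the previous 183 days; the start date itself is eligible (a
  documented boundary convention).
* Pill burden: total tablet quantity of non-diabetes prescriptions
  issued in the 91 days before the start, divided by 91 ("3 months" is
  exactly 91 days, matching the divisor). Quantity, not daily dose, is
  used because dose is the poorly recorded field. Liquid/injectable
  items are excluded — the measure counts tablets.
* Co-prescription flags (blood-pressure-lowering, lipid-lowering,
  antidepressant): any prescription of the category in the same 91-day
  window. Drug-code→category maps are configuration; the defaults are
  a small synthetic vocabulary because real BNF code lists are
  licence-bound.
* Charlson index: sum of standard weights over distinct conditions
  recorded on or before the start; the weight table is configuration
  with the original 17-condition weights as default.

Second-line rows carry the first line's capped MPR and non-adherence
flag; patients without a valid first-line MPR are excluded from the
second-line modelling set (a valid measure on both drugs is required).
Missingness is handled complete-case per model — a row missing BMI is
only dropped from models that use BMI; ethnicity keeps a `missing`
level and only restricts the models that include it. No imputation.

## 4. Models and metrics

Logistic regressions are fitted by IRLS (via statsmodels GLM/Binomial)
with convergence at relative log-likelihood change < 1e-8 within 100
iterations; complete separation is reported as `converged=False`, never
silently; rank-deficient designs raise an error naming the aliased
columns. Non-linear continuous predictors use simple linear splines
`(min(x, k), max(x − k, 0))` with knots at the turning points of the
association: age 70 (both lines) and 10 tablets/day (second line),
both overridable. The GAM-style shape check is implemented as a binned
empirical-logit curve (20 equal-count bins, +0.5 continuity
correction, 3-point moving average, turning points = sign changes of
the smoothed differences); it is advisory only, because knot choice
from such plots is inherently visual. The restricted-cubic-spline
sensitivity model uses the truncated-power natural-spline construction
(linear beyond boundary knots, scaled by the squared knot range), 4
knots at the 5th/35th/65th/95th percentiles by default — placement is
not prescribed anywhere, so quartile-ish coverage was chosen. For the
RCS likelihood-ratio test the reference is the same model with all
continuous terms linear, which the RCS model nests exactly.

Discrimination: the c-statistic is computed by midrank (Mann–Whitney)
counting with ties worth one half; Dxy = 2c − 1 holds to machine
precision; Nagelkerke R² = Cox–Snell/maximum. ROC curves sweep distinct
score values so the trapezoid area reproduces the pair-count
c-statistic. The MPR-bin curve (second-line non-adherence by
first-line MPR bin) uses Wilson 95% intervals — the interval method is
a package choice. The relative-risk CI uses the log-normal
approximation, cross-checked in tests against a bootstrap of the 2×2
table. No multiple-testing adjustment is applied anywhere.

The model ladder fitted by `run_study`: line-1 clinical; line-2
adherence-binary, adherence-continuous (capped), clinical, full
(clinical + adherence), full + ethnicity (on the ethnicity-recorded
subset, against the full model refitted on the same rows), and
full-RCS. The "share of log-likelihood explained by adherence" is
(LL_adherence − LL_0)/(LL_full − LL_0) with all three likelihoods
computed on the full model's rows.

## 5. The synthetic cohort generator

Each patient has latent adherence propensities p₁, p₂ ∈ (0, 1], one
per line, logit-normal with SD 1.0 on the logit scale. The two lines
share a Gaussian latent at correlation ρ (default 0.52) — the minimal
structure that makes first-line adherence predictive of second-line
adherence and yields the monotone risk-by-MPR-bin curve. Latent means
are auto-calibrated analytically so that P(p ≤ 0.80) is ≈ 19% (line 1)
and ≈ 14% (line 2); the ρ default was derived once from the
Gaussian-threshold identity for conditional non-adherence rates of
≈ 32% vs ≈ 9%, allowing for attenuation by refill-timing noise.

Covariate effects enter the propensity logit with weak slopes in the
reported directions: +0.015 per year of age below 70, +0.30 for
antidepressant use, −0.02 per tablet/day of pill burden (line 2).
Magnitudes are package defaults — nothing in routine summary
statistics pins them down — and are configurable.

Refill timing: the first fill is on day 0; subsequent gaps are
`supply/p` days with multiplicative lognormal jitter (SD 0.1, mean 1).
When refills continue past a year, the gap is widened by
`365p/(365p − supply/2)` so that the year-window MPR — which counts
the day-0 fill and whole supplies — is unbiased for p; episodes that
stop or switch are measured to a prescription date, where the plain
gap is already unbiased. The jitter model is a free design choice (no
distribution of refill gaps is published); its consequences are pinned
by tests: mean |MPR/100 − p| ≤ 0.05 for full-year patients, and the
fitted-model coefficient recovery checks.

Structural realism included: ~21% of prescriptions get dose recorded
as zero (exactly `round(0.21·N)` seeded-uniform rows); intensification
at a per-day hazard (default 0.0015 after a 90-day minimum);
registration windows, diagnosis dating from codes/HbA1c/prescriptions;
overdispersed (gamma-Poisson) co-medication counts so pill burden has
a genuine polypharmacy tail crossing the 10-tablet knot; ethnicity
~52% missing; and small deliberate sub-populations that exercise every
exclusion rule. Dates are integer day offsets; there is no calendar
arithmetic, UK prescribing seasonality, free-text dosing, or
practice-level clustering. Consequently, passing tests demonstrate the
*logic* of the pipeline and the qualitative reproducibility of the
adherence-predicts-adherence finding — not calibration to any real
population's coefficient values, which depend on licensed data.

All randomness flows from one integer seed through a single generator
stream; identical configuration and seed give byte-identical CSVs and
reports.

## 6. Problem sizes

Defaults were chosen to make a study run interactive: 2 000 simulated
patients per study (≈ 1 400 eligible, ≈ 1 200 second-line modelling
rows), 20 000 for the headline reproduction in
`scripts/acceptance.py`, and 20 000 for dependence-structure checks on
the latent stage. Logistic parameter-recovery checks use 20 replicates
of n = 50 000 drawn directly from the logistic model.

## 7. Known limitations

* MPR measures prescriptions issued, not collected or taken; it
  overestimates possession when supplies are stockpiled and cannot see
  primary non-collection.
* The generator's switch process is exogenous — in reality
  intensification timing correlates with adherence and HbA1c.
* In-sample c-statistics at a few hundred events are optimistic for
  the larger clinical models; the package deliberately mirrors the
  original in-sample evaluation rather than adding cross-validation.
* Episodes that stop or switch within the year have mildly attenuated
  MPRs relative to the latent propensity (the generator's unbiasedness
  correction targets the full-year window).
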