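# Methods

## Study design being modelled

The pipeline reimplements a cross-sectional EHR comparison of type 2
diabetes (T2DM) prevalence between patients with very low (median
≤ 60 mg/dl, never ≥ 80) and normal (median 90–130 mg/dl, never ≥ 150 or
≤ 80) LDL-cholesterol, where LDL-C is derived from lipid panels by the
Friedewald formula and measurements contaminated by statin exposure,
hospitalization, hypoalbuminemia or early childhood are removed first.
A two-phase design splits the cohort 1/3 : 2/3 — a permissive phecode
screen over the six T2DM phecodes with a Bonferroni gate (0.05/6), then a
high-specificity algorithmic phenotype analysed with adjusted logistic
regression, prespecified strata, interaction tests and sensitivity
restrictions.

## Synthetic-EHR generator

Real hospital records cannot be shipped, so the generator emulates the
features the pipeline consumes. All draws come from one `numpy`
`default_rng(seed)`; identical configuration ⇒ byte-identical tables.

**Demographics.** Sex: 57% female. Race: 69% European ancestry / 14%
African ancestry / 17% other. Age at the end of the record is log-normal,
group-dependent (low-LDL patients skew younger: median 33 vs 42.6 years),
clipped to 6–90 years. Record spans are log-normal (median 6.8 y,
σ = 0.8 on the log scale), capped by the 20-year simulation window and by
the patient's age.

**Lipids.** Per-patient latent levels: HDL ~ LogN(ln 51, 0.25);
triglycerides ~ LogN(ln 88, 0.45) low / LogN(ln 101, 0.40) normal; latent
LDL medians ~ LogN(ln 56, 0.16) low / LogN(ln 109, 0.12) normal. Each
panel records total cholesterol = LDL + HDL + TG/5 plus per-visit noise,
so the pipeline must recompute LDL-C; the low-group latent centre sits
above the observed target of ≈ 52 mg/dl because the median ≤ 60 / max < 80
eligibility rules truncate the upper tail — the defaults were calibrated
so the *post-selection* cohort medians land near 52 and 109 mg/dl.

**Outcome.** T2DM is a latent Bernoulli draw with log-odds
`−2.9 + ln(2)·1[low] + 0.045·(age−45) + 0.25·male + 0.40·AfricanAncestry
+ 0.09·(BMI−27)` by default (all effects configurable). This yields a
normal-group prevalence near 7%. T2DM-positive patients receive ≥ 2
type 2 ICD-9 codes on guaranteed-distinct days, an abnormal glucose
(130–240 mg/dl), HbA1c ≥ 6.6% with probability 0.5, metformin with
probability 0.8 and insulin with probability 0.3; negatives receive a
normal glucose (75–99 mg/dl) and no diabetes codes or medications. The
outcome is assigned from group membership, not continuous LDL — the
analysis contrast is group-based, so a continuous liability would add
machinery without changing what the pipeline can be tested against.

**Anchoring.** Every patient gets one generic ICD-9 code at the first and
last day of their record, so "age at most recent code" equals the age used
in the liability and EHR length equals the record span; BMI is recorded as
three repeat measurements with 1% multiplicative noise so the median
recovers the latent value. These choices make the fully adjusted model
correctly specified on synthetic data, which is what gives CI coverage
checks their meaning.

**Contamination.** Independent Bernoulli marks at configurable rates:
statin mention (10%, a random date; later panels become ineligible),
inpatient panels (5%), an albumin of 1.8–2.9 g/dl within ±15 days of the
first panel (3%), an extra panel before age 5 (2%), plus rarer features
for the sensitivity filters (ezetimibe 2%, ischemic-heart-disease codes
4%, advanced-renal codes 1%, eGFR ≤ 29 labs 1%, transplant codes 0.5%,
stroke/TIA codes 1%, direct LDL-C results on 5% of panels).

**What the generator does not emulate.** Care fragmentation across sites,
coding-intensity drift over calendar time, missing-not-at-random labs,
miscoded diagnoses (tests inject these explicitly where needed),
correlated lab batteries, and any genetic structure. Passing recovery
tests therefore demonstrates the pipeline's statistical correctness under
clean assumptions, not robustness to real-world record pathology.

## Cohort construction

Candidate LDL-C determinations are dates with a complete panel or a direct
LDL-C result (direct overrides Friedewald on the same date). Exclusion
reasons are applied in a fixed precedence order — inpatient → age < 5 →
albumin window → post-statin → TG > 400 — and only the first matching
reason is recorded, so attrition counts are reproducible. Numerical
conventions, chosen where the design was genuinely open:

* Group thresholds are read inclusively (median ≤ 60; "between 90 and
  130" as [90, 130]), matching the ≤/≥ style of the other rules.
* The albumin window is symmetric: |panel date − albumin < 3 g/dl date|
  ≤ 30 days.
* Friedewald values at TG > 400 mg/dl are invalid by standard clinical
  practice; the filter is on by default and configurable.
* A median above 130 mg/dl is recorded under `normal_out_of_band` (the
  exclusion vocabulary has no dedicated "median too high" value).
* The per-patient median of an even count is the mean of the two central
  values; the "median LDL date" (anchor of the adult-only sensitivity
  filter) is the eligible measurement closest in value to the median,
  earliest on ties.
* The discovery/validation split shuffles the union of both groups with a
  seeded generator and takes the first ⌊N/3⌋ patients as discovery.

## Phenotyping

Phecode calls use calendar-day counting: case at ≥ 2 distinct days with
ICD-9 codes mapping to the phecode or any prefix descendant; excluded at
exactly 1 day, or at 0 days when any of the patient's codes maps into the
phecode's numeric exclusion ranges; control otherwise. The bundled map is
a miniature synthetic subset (diabetes 250.*, ischemic heart disease
411.*, CKD 585.3x) sufficient for the analysis; a full external map in the
same schema can be supplied.

The algorithmic T2DM classifier is a fixed, documented proxy for
published high-PPV electronic phenotyping rules: case requires a type 2
code (250.x0/250.x2) *and* supporting evidence (diabetes medication,
glucose ≥ 126 mg/dl, or HbA1c ≥ 6.5%) *and* no type-1-only pattern
(exclusively 250.x1/250.x3 with insulin and no oral agent); control
requires no diabetes-range codes, no diabetes medications and a normal
glucose < 100 mg/dl; everyone else is excluded. The glycemic thresholds
are ADA conventions — the source algorithm's internal cutoffs are not
published in a form this package could cite, so the proxy's rules are
fixed here and tested as such.

## Association models

* 2×2 tables use the Woolf closed form: OR = ad/bc, CI =
  exp(ln OR ± z·√(1/a+1/b+1/c+1/d)); a zero cell raises an error
  suggesting the optional Haldane–Anscombe 0.5 correction (off by
  default).
* Adjusted models are binomial-logit GLMs fitted by IRLS (statsmodels;
  tolerance 1e-8, ≤ 50 iterations) with Wald intervals everywhere,
  matching the normal-approximation style of the 2×2 interval. Race
  enters as two indicators against a European-ancestry reference, with
  "other" retained as a level but not reported as a stratum.
* Separation policy: a degenerate outcome or single-level exposure raises
  immediately; post-fit, any |coefficient| or standard error above 20 on
  the log-odds scale marks the fit `converged=False` with a diagnostic —
  never a silent estimate.
* Complete-case analysis per fit, with the per-fit N carried on every
  result row.
* BMI strata follow the WHO convention (normal 18.5–<25, overweight
  25–<30, obese ≥ 30); underweight patients stay in the primary model but
  not in BMI-stratified fits. The LDL refinement uses a strict < 40 and an
  inclusive [40, 60].
* Sensitivity filters treat "previous medical condition" as any qualifying
  code — or eGFR ≤ 29 ml/min lab — dated up to 30 days after the first
  qualified LDL-C measurement; restrictions 2a–2c are cumulative, so their
  cohorts nest. ICD-9 334.9 appears verbatim in the stroke/TIA/PVD list
  (as printed in the source material, although it denotes cerebellar
  ataxia); a configuration switch substitutes 433.91.

## Monte-Carlo validation scales

CI coverage runs 100 seeds at the default n = 20,000 with true OR 2.0;
the interaction type-I check runs 200 seeds at n = 6,000 using the sex
interaction, whose cells are large and balanced enough for the Wald test
to be well calibrated at that size (the race interaction has a small
exposed-minority-case cell and would confound calibration of the test
with small-sample Wald behaviour). Base seeds are fixed constants so the
checks are deterministic.

## Known limitations

* The discovery screen is marginally powered at the default 20,000-patient
  scale — the emulated study's discovery sample was ~27,000 strong on its
  own — so the Bonferroni gate passes or fails depending on the seed;
  `force_validation` exists precisely for recovery experiments.
* The unadjusted odds ratio on synthetic data is *not* the generator's
  true OR: the low group is younger and leaner by construction, and the
  logistic OR is non-collapsible, so only the fully adjusted conditional
  estimate targets the configured effect.
* Manual chart review (used in the original design for LDL-C < 20 mg/dl)
  has no automatable counterpart and is not modelled.
* Real-data adjusted effect sizes cannot be reproduced because the
  underlying records are not public; the package validates its estimator
  by parameter recovery instead.
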