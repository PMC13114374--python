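# Methods

## The composite score

The Neuro–Cardio–Renal Stress Index is an additive composite of three
integer domain scores computed per patient from a delimited EMR export.
The design is deliberately transparent: fixed rules and literature-style
thresholds, no regression weighting, latent-variable modelling or
data-driven calibration. All units are fixed by contract (creatinine,
glucose, triglycerides in mg/dL; UACR in mg/g; age in years) because both
core formulas are unit-specific.

**Neuro-psychic domain (0–3).** Free text is normalized (lowercased,
diacritics stripped via Unicode NFKD decomposition, whitespace collapsed)
and matched against keyword dictionaries by substring search. One point per
satisfied accumulation rule: ≥1 distinct symptom category documented, ≥2
distinct categories, and ≥1 psychotropic medication class in the medication
field. A documented severe psychiatric condition (e.g. bipolar disorder,
schizophrenia) forces at least 2 points. The rule set expresses
*accumulation of documented indicators*, not severity, and is exposed as
configuration: the bundled English/Romanian dictionaries are stand-ins, and
real deployments should supply site-specific term lists. Negation and
temporality are not handled — a documented limitation of rule-based EMR
phenotyping, which can both under-classify and misclassify.

**Cardiometabolic domain (0–3).** TyG = ln(triglycerides × glucose / 2).
Band points: TyG < 8.5 → 0, 8.5 ≤ TyG < 9.0 → 1, ≥ 9.0 → 2; these cut-offs
sit near widely used insulin-resistance bands and are configuration, with a
±0.2 perturbation built into the sensitivity runner. One further point if
any cardiometabolic diagnosis (hypertension, diabetes, dyslipidemia,
obesity/metabolic syndrome) is documented.

**Renal domain (0–4).** eGFR from the IDMS-traceable 4-variable MDRD
equation (coefficient 175, female factor 0.742, no ethnicity factor; the
older 186-coefficient form differs by a constant ratio and is not used).
KDIGO stages are left-closed at each lower bound, so eGFR = 60 is G2
(preserved function) and scores 0. Points: G1/G2 → 0, G3a → 1, G3b → 2,
G4 → 3, G5 or dialysis → 4. UACR is carried descriptively (correlation
matrix) but never enters point allocation.

Totals partition into low (0–3), moderate (4–6) and high (7–10). Patients
are also labelled by multimorbidity context: *cardiometabolic* (≥1
cardiometabolic diagnosis, eGFR ≥ 60), *renometabolic* (diagnosis with
eGFR < 60) and *other*.

**Complete-case screen.** Scoring requires glucose, triglycerides,
creatinine and a non-empty diagnosis text; records missing any of these are
excluded and itemized in a report that accounts for every screened record.
Missing medication text does not exclude a record — it only forfeits
psychotropic points.

## Alternative weightings

Two symmetric formulations probe how much of the renal domain's statistical
dominance is structural:

- `symmetric_3` (0–3/0–3/0–3, total 0–9): collapses G4 with G5/dialysis at
  3 renal points; N and C unchanged.
- `symmetric_4` (0–4/0–4/0–4, total 0–12): keeps the renal mapping and
  widens N and C monotonically — a fourth accumulation rule (≥3 distinct
  categories) and a TyG ≥ 9.5 band. Any record's points under the wider
  scheme are ≥ its points under the original.

Category boundaries on non-original scales rescale proportionally with
round-half-up (0–9: low ≤ 3, moderate ≤ 5; 0–12: low ≤ 4, moderate ≤ 7),
since the published bands are defined only for the 0–10 scale.

A domain's variance *contribution* is its covariance share,
cov(domain, total) / var(total) — chosen because it is the only additive
decomposition whose three parts sum exactly to 100%; raw per-domain
variances are reported alongside. Spearman correlations use mid-ranks with
the large-sample t-approximation p-value (the n ≈ 143 regime); constant
inputs yield an explicit NaN-with-warning, never a silent zero. Missing
UACR is handled pairwise-complete. Group contrasts use tie-corrected
Kruskal–Wallis tests. Everything is interpreted descriptively; no
multiple-testing correction is applied.

## Charlson proxy

For contextual benchmarking only, a text-derived Charlson Comorbidity Index
flags the categories reliably detectable in free text (heart failure,
cerebrovascular disease, dementia, chronic pulmonary disease, diabetes,
malignancy) with their original weights, plus moderate/severe renal disease
(weight 2) defined objectively as eGFR < 60 or documented dialysis.
Diabetes is scored uncomplicated (weight 1). Age adjustment adds one point
per decade from 50–59, capped at 4 for ≥ 80. Categories not detectable in
text contribute zero, so the proxy underestimates a full administrative
CCI.

## Synthetic cohort generator

The generator produces seeded cohorts with the three-group structure
(48 cardiometabolic / 82 renometabolic / 13 other) so that every pipeline
stage is testable without patient data. Group-level biomarker targets:
mean eGFR ≈ 88.6 / ~53 / 76.8 mL/min/1.73 m², TyG 9.14 / 9.16 / 8.73,
chronic medications 5.87 / 7.07 / 5.08.

Design choices:

- **Stage-quota renal sampling.** Each group carries exact per-stratum
  counts with eGFR uniform within the stratum band (e.g. the renometabolic
  group: 65 patients in G3a, 9 in G3b, 5 in G4, 3 in G5 on dialysis), and
  creatinine is obtained by exact inversion of the MDRD equation against
  the sampled age and sex. Records therefore carry only raw fields, and the
  renal structure — including the staged left tail that drives the strong
  R-vs-eGFR rank correlation — is represented faithfully at n = 82 rather
  than left to small-sample luck.
- **Feasibility compromise on the renometabolic mean.** A group mean of
  exactly 53.21 under the hard eGFR < 60 ceiling is incompatible with any
  meaningful G3b/G4/G5 tail: the algebra forces the G3a bulk above the
  ceiling. The shipped strata give a design mean ≈ 51.5, within the ±3
  tolerance the generator promises for realized group means, while keeping
  a clinically sensible stage mix.
- **TyG back-solving.** TyG is sampled directly (normal, SD 0.35, clipped
  to a physiologic window) and triglycerides are solved from a log-normal
  glucose draw, preserving the sampled index exactly; labs are clamped to
  physiologic bounds (creatinine 0.3–15, glucose 50–500, triglycerides
  30–1000 mg/dL).
- **Text assembly.** Diagnosis strings are assembled from per-category
  Romanian/English surface pools with diacritics and mixed case (so the
  normalization path is exercised end to end), per-group category
  prevalences, and distractor strings that match no dictionary — a built-in
  negative control. The "other" group carries no cardiometabolic keyword,
  so group membership is recoverable from the generated data alone.
- **Dispersions are guesses.** The emulated study conditions specify group
  means only; SDs, prevalences and age distributions are scenario
  parameters with documented defaults in `data/default_study.yml`, chosen
  once for clinical plausibility.

What passing tests on this cohort do and do not show: they demonstrate the
*structural* behaviour of the index — the sign pattern of the correlation
matrix, the graded group medians, the direction of the weighting and
threshold sensitivities — under clean, well-separated group definitions.
They do not reproduce a real cohort's joint distribution, documentation
noise, negated mentions, or the exact published correlation magnitudes, and
they say nothing about construct validity of the neuro-psychic proxy.

## Numerical notes

- TyG cut-offs are compared left-closed (TyG = 8.5 earns the first band
  point), mirroring the left-closed stage bounds.
- The complete-case filter and missingness injection are deterministic per
  seed; generation uses one `numpy` Generator consumed in record order.
- Spearman/Kruskal–Wallis are delegated to scipy.stats behind the module
  API; the test suite checks both against independent hand-rank oracles to
  1e-9 on small vectors with ties.
- `variance_shares` raises on a constant total rather than returning 0/0.
- Problem sizes throughout (143-patient default cohort, 10× scaling for
  calibration checks) keep the full test suite and the acceptance script
  in the seconds range.
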