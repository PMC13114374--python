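# Default synthetic-cohort scenario: three multimorbidity contexts with
# group sizes 48 / 82 / 13 and biomarker marginals emulating the study
# conditions (group mean eGFR ~ 88.6 / ~53 / 76.8; TyG 9.14 / 9.16 / 8.73;
# chronic medications 5.87 / 7.07 / 5.08). eGFR is drawn from per-stage
# quota strata (exact counts, uniform within band) and converted to serum
# creatinine by inverting the MDRD equation, so records carry raw labs only.
# Within-group dispersions are scenario guesses: the source marginals are
# means without spread.

female_prob: 0.55

groups:
  - name: cardiometabolic
    size: 48
    egfr_strata:           # count, lower, upper (mL/min/1.73 m^2)
      - {count: 22, lo: 90.0, hi: 119.4}
      - {count: 26, lo: 62.0, hi: 88.0}
    age: {mean: 61, sd: 9, lo: 35, hi: 88}
    tyg: {mean: 9.14, sd: 0.35, lo: 8.2, hi: 10.2}
    glucose: {median: 105, sigma: 0.15}
    meds_mean: 5.87
    uacr: {mean: 17.32, sigma: 0.7, missing: 0.2}
    cardiometabolic_dx:
      hypertension: 0.85
      diabetes: 0.45
      dyslipidemia: 0.50
      obesity_metsyn: 0.30
    charlson_dx:
      chf: 0.08
      pulmonary: 0.10
      cerebrovascular: 0.05
      malignancy: 0.03
      dementia: 0.01
    neuro_prevalence:
      anxiety: 0.45
      depressive: 0.35
      sleep: 0.40
      psychosomatic: 0.25
      cognitive: 0.15
      severe_psychiatric: 0.02
    psychotropic_prevalence:
      anxiolytic: 0.32
      antidepressant: 0.32
      antipsychotic: 0.04

  - name: renometabolic
    size: 82
    egfr_strata:
      - {count: 65, lo: 55.5, hi: 59.8}
      - {count: 9, lo: 31.0, hi: 44.0}
      - {count: 5, lo: 16.0, hi: 29.5}
      - {count: 3, lo: 6.0, hi: 10.0, dialysis: true}
    age: {mean: 69, sd: 9, lo: 40, hi: 92}
    tyg: {mean: 9.16, sd: 0.35, lo: 8.2, hi: 10.2}
    glucose: {median: 112, sigma: 0.15}
    meds_mean: 7.07
    uacr: {mean: 32.09, sigma: 0.7, missing: 0.2}
    cardiometabolic_dx:
      hypertension: 0.90
      diabetes: 0.50
      dyslipidemia: 0.50
      obesity_metsyn: 0.25
    charlson_dx:
      chf: 0.15
      pulmonary: 0.10
      cerebrovascular: 0.08
      malignancy: 0.04
      dementia: 0.04
    neuro_prevalence:
      anxiety: 0.45
      depressive: 0.35
      sleep: 0.40
      psychosomatic: 0.25
      cognitive: 0.20
      severe_psychiatric: 0.02
    psychotropic_prevalence:
      anxiolytic: 0.32
      antidepressant: 0.32
      antipsychotic: 0.04

  - name: other
    size: 13
    egfr_strata:
      - {count: 10, lo: 70.0, hi: 99.9}
      - {count: 2, lo: 50.0, hi: 58.0}
      - {count: 1, lo: 38.0, hi: 44.0}
    age: {mean: 57, sd: 12, lo: 25, hi: 85}
    tyg: {mean: 8.73, sd: 0.35, lo: 7.8, hi: 9.8}
    glucose: {median: 98, sigma: 0.15}
    meds_mean: 5.08
    uacr: {mean: 45.74, sigma: 0.7, missing: 0.2}
    cardiometabolic_dx: {}
    charlson_dx:
      chf: 0.05
      pulmonary: 0.20
      cerebrovascular: 0.05
      malignancy: 0.08
      dementia: 0.05
    neuro_prevalence:
      anxiety: 0.60
      depressive: 0.50
      sleep: 0.55
      psychosomatic: 0.45
      cognitive: 0.25
      severe_psychiatric: 0.08
    psychotropic_prevalence:
      anxiolytic: 0.50
      antidepressant: 0.50
      antipsychotic: 0.08

# Surface forms used to assemble diagnosis text. Mixed-case Romanian/English
# with diacritics, exercising the normalization path; each surface contains
# at least one term of its category's dictionary once normalized.
diagnosis_surfaces:
  hypertension: ["HTA esențială", "Hipertensiune arterială", "hypertension stage 2"]
  diabetes: ["Diabet zaharat tip 2", "diabet zaharat tip II", "type 2 diabetes"]
  dyslipidemia: ["Dislipidemie mixtă", "hipercolesterolemie", "dyslipidemia"]
  obesity_metsyn: ["Obezitate gradul II", "sindrom metabolic", "obesity"]
  anxiety: ["Tulburare anxioasă", "Anxietate generalizată", "anxiety disorder", "atacuri de panică"]
  depressive: ["Tulburare depresivă recurentă", "Episod depresiv moderat", "depression", "sindrom anxios-depresiv"]
  sleep: ["Insomnie cronică", "insomnia", "tulburări de somn"]
  psychosomatic: ["Distonie neurovegetativă", "tulburare psihosomatică", "somatizare"]
  cognitive: ["Tulburări cognitive ușoare", "tulburări de memorie", "mild cognitive impairment"]
  severe_psychiatric: ["Tulburare afectivă bipolară", "Schizofrenie paranoidă", "psihoză"]
  chf: ["Insuficiență cardiacă NYHA II", "heart failure"]
  cerebrovascular: ["Sechele AVC", "stroke"]
  dementia: ["Demență mixtă", "boala Alzheimer"]
  pulmonary: ["BPOC", "Astm bronșic", "bronșită cronică"]
  malignancy: ["Neoplasm mamar operat", "neoplazie colonică"]

medication_surfaces:
  anxiolytic: ["Alprazolam 0.25 mg", "Bromazepam", "Hidroxizin"]
  antidepressant: ["Sertralină 50 mg", "Escitalopram", "Mirtazapină"]
  antipsychotic: ["Quetiapină 25 mg", "Olanzapină"]

# Negative controls: plausible chronic-disease strings that must match no
# dictionary category.
distractor_diagnoses:
  - "Gonartroză bilaterală"
  - "Osteoporoză"
  - "Gastrită cronică"
  - "Hipotiroidism"
  - "Lombalgie cronică"
  - "Hernie de disc"
  - "Litiază biliară"

# Non-psychotropic medication fillers for the medication field.
medication_fillers:
  - "Metoprolol"
  - "Atorvastatină"
  - "Metformin"
  - "Perindopril"
  - "Aspenter"
  - "Furosemid"
  - "Pantoprazol"

dialysis_phrase: "Program de hemodializă cronică"
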