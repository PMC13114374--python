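# Bundled keyword dictionaries for rule-based phenotyping (stand-in lists).
# Terms are matched as substrings of normalized text (lowercase, diacritics
# stripped), so stems like "anxiet" cover anxiety / anxietate / anxietatii.
# English and Romanian clinical vocabulary mixed; replace with site-specific
# lists for real EMR extractions.

# --- neuro-psychic categories (diagnosis text) ---
anxiety:
  - anxiet            # anxiety, anxietate
  - anxio             # anxios, anxioasa
  - anxious
  - panic             # panica, atac de panica, panic attack
depressive:
  - depres            # depression, depresie, depresiv
  - dysthymia
  - distimie
sleep:
  - insomni           # insomnia, insomnie
  - sleep disturbance
  - tulburari de somn
  - hipersomnie
psychosomatic:
  - psihosomatic
  - psychosomatic
  - somatizare
  - somatization
  - distonie neurovegetativa
  - neurastenie
cognitive:
  - tulburari cognitive
  - cognitive impairment
  - tulburari de memorie
  - memory complaints
  - deficit cognitiv
severe_psychiatric:
  - schizofreni        # schizofrenie, schizophrenia
  - schizophreni
  - bipolar
  - psihoza
  - psychosis

# --- cardiometabolic diagnoses (diagnosis text) ---
hypertension:
  - hipertensiune
  - hypertension
  - hta
diabetes:
  - diabet             # diabet zaharat, diabetes
  - t2dm
dyslipidemia:
  - dislipidemie
  - dyslipidemia
  - hipercolesterolemie
  - hypercholesterolemia
  - hiperlipidemie
obesity_metsyn:
  - obezitate
  - obesity
  - sindrom metabolic
  - metabolic syndrome

# --- Charlson categories detectable in text (diagnosis text) ---
chf:
  - insuficienta cardiaca
  - heart failure
cerebrovascular:
  - avc                # accident vascular cerebral
  - stroke
  - cerebrovascular
  - atac ischemic tranzitor
dementia:
  - dement             # dementa, dementia
  - alzheimer
pulmonary:
  - bpoc
  - copd
  - astm bronsic
  - asthma
  - bronsita cronica
  - chronic bronchitis
  - emfizem
malignancy:
  - neoplasm
  - neoplazie
  - cancer
  - carcinom
  - limfom
  - leucemie
  - tumora maligna

# --- psychotropic medication classes (medication text) ---
anxiolytic:
  - alprazolam
  - bromazepam
  - lorazepam
  - diazepam
  - medazepam
  - hydroxyzin         # hydroxyzine
  - hidroxizin
antidepressant:
  - sertralin          # sertraline, sertralina
  - escitalopram
  - paroxetin
  - fluoxetin
  - venlafaxin
  - duloxetin
  - mirtazapin
  - trazodon
  - amitriptilin
antipsychotic:
  - olanzapin
  - quetiapin
  - risperidon
  - haloperidol
  - aripiprazol

# --- dialysis (diagnosis or medication text) ---
dialysis:
  - dializa
  - dialysis
  - hemodializa
  - hemodialysis
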