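"""Score a small hand-written cohort table and read the result.

Builds a three-patient CSV, applies the complete-case screen, and prints
each patient's domain points, composite total, risk category and
multimorbidity group.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from ncrsi import complete_case_filter, read_cohort, score_cohort

CSV = """patient_id,age,sex,creatinine,glucose,triglycerides,n_medications,diagnosis_text,medication_text
P1,58,female,0.9,98,132,4,HTA; Anxietate generalizată; Insomnie cronică,Perindopril; Alprazolam
P2,74,male,1.8,141,205,9,Diabet zaharat tip 2; dislipidemie; sechele AVC,Metformin; Atorvastatină
P3,66,female,1.1,,150,5,Tulburare depresivă,Sertralină
"""

with TemporaryDirectory() as tmp:
    path = Path(tmp) / "cohort.csv"
    path.write_text(CSV, encoding="utf-8")
    records = read_cohort(path)

retained, report = complete_case_filter(records)
print(f"screened {report.n_screened}, included {report.n_included}")
for pid, missing in report.excluded_ids:
    print(f"  excluded {pid}: missing {missing}")

scores = score_cohort(retained)
print(scores[["patient_id", "n_points", "c_points", "r_points", "total",
              "category", "group", "egfr", "ckd_stage", "tyg"]].round(2).to_string(index=False))

# P1: anxiety + sleep categories and an anxiolytic accumulate neuro points;
# preserved renal function keeps R at 0. P2: reduced eGFR plus an elevated
# TyG and documented diagnoses push the total into the moderate/high range.
# P3 is excluded: no fasting glucose, so TyG cannot be computed.
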