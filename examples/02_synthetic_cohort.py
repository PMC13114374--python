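"""Generate the default seeded synthetic cohort and summarize it.

The scenario emulates three multimorbidity contexts (48 cardiometabolic,
82 renometabolic, 13 other) with group mean eGFR near 88.6 / ~53 / 76.8
and TyG near 9.14 / 9.16 / 8.73. Records carry only raw fields; every
derived biomarker is recomputed by the scoring pipeline.
"""

from ncrsi import default_scenario, generate, group_summary, score_cohort

records = generate(default_scenario(), seed=1)
scores = score_cohort(records)

print(scores.groupby("group")[["egfr", "tyg", "n_medications"]].mean().round(2))
summary = group_summary(scores)
print("median totals:", summary["group_medians"])
print(summary["category_counts"])
# The renometabolic group concentrates the moderate-to-high categories,
# the heterogeneous "other" group sits mostly in the low band — the graded
# pattern the composite is designed to express.
h, p = summary["kw_results"]["total"]
print(f"Kruskal-Wallis on totals: H = {h:.1f}, p = {p:.2g}")
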