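"""Compare domain weightings: original 3/3/4 vs symmetric 3/3/3 and 4/4/4.

Prints each domain's covariance share of the composite variance and the
Spearman correlation between the total and each domain, under all three
schemes on the same synthetic cohort.
"""

from ncrsi import default_scenario, generate, weighting_sensitivity

records = generate(default_scenario(), seed=1)
table = weighting_sensitivity(records)
print(table.round(3).to_string())

# The renal share shrinks when the 0-4 renal scale is collapsed to 0-3
# (symmetric_3): part of the renal domain's statistical dominance in the
# original formulation is structural — it comes from the asymmetric point
# allocation, not from the biology of the cohort.
original = table.loc["original", "share_r"]
symmetric = table.loc["symmetric_3", "share_r"]
print(f"renal share: {original:.1%} (original) -> {symmetric:.1%} (equal weighting)")
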