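"""Paired tumor-vs-normal expression comparison on a matched synthetic cohort.

Generates 24 matched tumor/normal pairs with a planted 4-fold (2 on the log2
scale) increase in the tumor samples and tests it with the paired t-test on
log2(x+1) values, printing the conventional significance stars.
"""

from taascan import expression as xp, synthetic_data as sd

matrix = sd.gen_expression_matrix(
    sd.SimulationConfig(seed=3, n_pairs=24, log2_fold_change=2.0), gene="MDK"
)

result = xp.paired_compare(matrix, "MDK")
stars = xp.significance_stars(result.p_value)
direction = {1: "up in tumor", 0: "no change", -1: "down in tumor"}[result.direction]

print(f"paired t statistic : {result.statistic:.2f} over {result.n} pairs")
print(f"p value            : {result.p_value:.2e}  ({stars})")
print(f"direction          : {direction}")
# A planted 4-fold change over 24 pairs is detected at p << 0.0001 (****),
# the level reported for strongly tumor-overexpressed genes.
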