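"""Pairwise PPT-prevalence comparisons between the history categories.

Each pair of categories forms a 2x2 table (PPT yes/no); the uncorrected
Pearson chi-square or Fisher's exact test is chosen by expected counts and
p-values are Bonferroni-adjusted over the 28 comparisons.
"""

from pptscreen import (
    Category,
    TwoByTwo,
    odds_ratio,
    pairwise_ppt_tests,
    reconstruct_reference_cohort,
    stratum_table,
)

table = stratum_table(reconstruct_reference_cohort())
counts = {c: (table.category_totals(c).n, table.category_totals(c).n_ppt) for c in Category}
grid = pairwise_ppt_tests(counts)
significant = grid[grid.p_adjusted < 0.05]
print(significant.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
print(f"\n{len(significant)} of 28 pairs significant after Bonferroni correction")

# Cohort-level odds ratios for each history item (PPT vs no PPT):
for name, cells in [
    ("familial autoimmune non-thyroid disease", (43, 20, 148, 201)),
    ("personal autoimmune non-thyroid disease", (29, 34, 80, 269)),
    ("familial thyroid disease", (27, 36, 100, 249)),
]:
    print(f"OR {name}: {odds_ratio(TwoByTwo(*cells)):.2f}")
# All significant pairs involve the high-risk categories II or IV; the two
# autoimmune-history items nearly triple the odds of postpartum thyroiditis.
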