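"""The three-level risk partition driven by history and seafood consumption.

Crossing the eight history categories with the five fish groups splits the
cohort into a very-high-risk tier (monitor postpartum, no assay needed), a
low-risk tier (neither assay nor monitoring) and an intermediate tier that
gets selective gestational antibody screening.
"""

from pptscreen import RiskTier, reconstruct_reference_cohort, stratum_table

table = stratum_table(reconstruct_reference_cohort())
for tier in RiskTier:
    t = table.tier_totals(tier)
    print(
        f"{tier.value:>12}: {t.n:3d} women, {t.n_ppt:2d} PPT "
        f"({100 * t.n_ppt / t.n:.1f}%), {t.n_ph:2d} PH"
    )
# very_high: 26 women of whom 25 (96%) develop PPT -- monitoring is mandatory;
# low: 200 women with a 3.5% PPT rate -- screening can be skipped entirely;
# intermediate: the remaining 186 women are the selective-screening target.
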