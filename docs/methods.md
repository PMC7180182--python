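# Methods

## Cohort model

A participant is a tuple (three binary histories, fish group A–E, four nested
antibody flags, PPT, PH). The three histories — familial thyroid disease,
familial autoimmune non-thyroid disease (AINTD), personal AINTD — are strictly
binary (the questionnaire admits only positive/negative; there is no
"unknown" level) and map bijectively onto categories I–VIII. PH is nested
within PPT by construction: a record with PH but no PPT is rejected at
parse/construction time with its id.

The risk tier is a pure function of (category, fish group). The very-high
tier is all of category II, group A of category III, and category IV except
group B; the intermediate tier is I×{A,D}, IV×B, V×B, VI×{A,B,C,D},
VII×{A,C,E}, VIII×{A,B,D}; everything else is low. Three strata never occur
in the reference cohort (II×B, III×{B,D,E}, VIII×E); the tier function is
nevertheless total, extending the defining set rules literally: II×B is
very-high ("all of category II"), and the III/VIII strata named by neither
the very-high nor the intermediate list default to low. Simulated cohorts can
populate these strata, so totality matters; the assignment is overridable via
the `overrides` argument of `risk_tier` for sensitivity analyses.

## Reference-cohort reconstruction

The packaged transcription (`data/table2.csv`) holds the printed
(category × fish group) cell counts: n, PPT and PH per cell. Expansion is
deterministic: within each cell, PPT+PH cases first, then PPT-only, then
unaffected, ids `W0001`–`W0412`. One correction is applied on load: the
printed PH cells sum to 35, while the category totals, the 34-PH cohort
total and the tier-level PH aggregates all require 34, with category VI
contributing 1 rather than the printed 2. Both candidate cells (VI×B and
VI×C, each printed 1/1) lie in the intermediate tier, so either may be
zeroed without disturbing any other printed aggregate; the reconstruction
fixes VI×B to 0 and keeps VI×C at 1. Two further printing oddities in the
source table headers (category VI shown as "n = 4" where the column and the
totals row give 46; the group-E PPT row labelled "n = 14" where its cells
sum to 4) are resolved in favour of the cell values and totals row.

The verification report (`verify_reference_cohort`) checks 133 aggregates —
cohort totals, all 80 per-cell (n, n_ppt) values, category margins, tier
sizes/PPT/PH, and the screening populations, detections and PH-detections of
all eleven strategies — against constants embedded independently of the
input transcription, so a corrupted input is caught and named cell by cell.

## Antibody-flag allocation

No per-woman antibody results are published; what is published is, for each
threshold level L ∈ {TPOAb>100, TPOAb>60, anyAb>100, anyAb>60}: the
positives and true positives in the whole cohort (strategies [d]–[g]) and
within the 186-woman intermediate tier ([h]–[k]), and PH among each
strategy's detected cases. The allocator reproduces all of these *exactly*:

1. Each woman gets one of five mutually exclusive flag classes —
   TPOAb>100; TPOAb∈(60,100] with TgAb≤100; TgAb>100 with TPOAb≤60;
   TgAb∈(60,100] with TPOAb≤60; negative — which determine the four nested
   flags. The sixth conceivable class (TPOAb∈(60,100] *and* TgAb>100) is
   deliberately left empty: no published aggregate requires it, and with it
   empty the decomposition of the nested level counts into class counts is
   unique (successive differences).
2. Level counts are decomposed into per-class quotas separately for the
   intermediate tier and its complement, for positives, true positives and
   PH-positive true positives (the selective strategies' PH counts first
   subtract the very-high tier's monitored PH cases). Any negative quota or
   quota exceeding the available pool raises an error naming the first
   violated constraint.
3. Quotas are filled greedily and deterministically: tightest class first,
   within each class PH-positive PPT cases, then PH-negative PPT cases, then
   unaffected women, in the reconstruction's record order. A final audit
   recounts every constrained aggregate.

The published constraint set is feasible (the test suite asserts the
allocator finds a solution with no manual seeding), and allocation is
idempotent. The positivity threshold is 60 U/ml wherever "upper part of the
reference range" is meant (the source text alternately says "midpoint" —
50 — and ">60"; the printed counts are consistent with 60, which is used
throughout). An optional helper draws continuous titres uniform within each
flag's band for downstream tooling; the study prints no per-woman titres, so
these are synthetic conveniences.

## Strategies, metrics, costs

Detection equals monitoring ∧ PPT: every monitored woman who develops PPT is
counted as caught; the four-visit monitoring schedule affects cost only,
never sensitivity. Strategy [b] monitors by category membership (II∪III∪IV,
31 women) ignoring fish groups; [c] monitors the very-high tier (26).

Metrics use the study's denominators: false-positive rate = FP/monitored
(= 1−PPV), false-negative rate = FN/unmonitored (= 1−NPV), accuracy =
(TP+TN)/cohort. For universal monitoring ([a]) the study books no false
positives — monitoring everyone is surveillance, not a diagnostic claim — so
`confusion` sets FP = 0 and TN = the non-PPT count when given a strategy with
the universal monitoring rule. Undefined denominators yield absent (`None`)
metrics, never zero.

Costs: gestational = screened × panel size × analyte price (default Euro
10); monitoring = monitored × visits × analytes/visit × price (default
4 × 2 × 10 = 80). Per-case costs are exact quotients; rounding is display
only (two decimals). The 1,000-woman projection scales each population by
1000/412 and rounds to the nearest whole woman (half away from zero) before
costing; this reproduces the published projection row for nine of the eleven
strategies, while the published values for [f] (34,800 vs computed 34,720)
and [g] (38,100 vs 38,080) deviate from any single consistent rounding rule
and are annotated rather than forced.

### Annotated inconsistencies in the published strategy table

The report always shows values computed from the table's own confusion
counts and flags these entries: [b] accuracy printed 350/412 (84.9%) vs
TP+TN = 370 (89.8%); [b] false-negative rate printed 17.6% vs its own
fraction 37/381 = 9.7%; [c] PPT-missed printed 60.4% vs 38/63 = 60.3%;
[d] specificity fraction printed 323/349 where the percentage (95.1%) and
NPV row imply 332/349; [e] specificity printed 92.5% vs 92.55 → 92.6%;
[f] false-negative denominator printed as TN (321) rather than TN+FN (336);
per-case costs printed at one decimal for [a] (523.20; exact 523.17),
[b] (95.40; 95.38) and [g] per-PH (540.70; 540.69).

## Contingency statistics

`pearson_chi2` is the uncorrected statistic n(ad−bc)²/((a+b)(c+d)(a+c)(b+d))
with p from χ²₁; `fisher_exact` is the two-sided sum of hypergeometric
probabilities ≤ the observed table's (verified in tests against a brute-force
enumeration oracle on small tables); Bonferroni uses m = 28 (all pairs of 8
categories) by default. `choose_test` applies the conventional rule — Fisher
when any expected cell count is below 5 — but the published pairwise grid
reports χ² statistics even for pairs involving the small categories II and
IV, so `run_test`/`pairwise_ppt_tests` accept `rule="chi2"`/`"fisher"` to
force a test. The printed χ² statistics all reproduce from the category
counts to the printed precision; two (IV–VII 37.7, IV–VIII 30.1) compute to
37.75 and 30.15, i.e. the source rounded them down by half a printing unit.
Odds ratios are the plain cross-product ad/bc with no continuity adjustment,
undefined (not zero) when b·c = 0.

## Synthetic sampler

`SamplerParams.from_reference()` calibrates to the reconstructed cohort:
stratum probabilities = cell sizes / 412, per-stratum PPT and PH-given-PPT
rates, and flag-class probabilities conditional on (risk tier, PPT status) —
the finest conditioning the calibrated allocation supports. Sampling is
i.i.d. per woman from a single `numpy` generator, so identical seeds give
identical cohorts and flags respect the nesting invariants by construction.
What the sampler emulates is exactly the stratified prevalence structure of
the reference cohort; what it does not emulate: within-stratum covariate
correlation beyond the tier-level flag conditioning, titre magnitudes,
longitudinal hormone trajectories, or the thyrotoxic/hypothyroid phase
structure of PPT. Tests passing on sampled cohorts therefore speak to the
published aggregate structure, not to unmodelled features of real cohorts.

The parameter-recovery test draws 100,000 women and checks each
non-degenerate stratum's PPT-rate estimate against a 99% *family-wise*
normal band (Bonferroni-adjusted across the ~37 strata tested jointly;
per-stratum 99% bands applied jointly would fail by design ~30% of the
time). Degenerate strata (rate 0 or 1) must be recovered exactly.

## Problem sizes and determinism

Everything headline-level is deterministic and runs on the 412-woman cohort
in well under a second; the simulation example uses 100 replicates of 412
women and the recovery test one draw of 100,000, keeping the full test suite
at a few seconds. Replicate seeds are spawned from the base seed via
`numpy.random.SeedSequence` and kept below 2³¹.

## Known limitations

Unit costs are flat out-of-pocket prices for one region and era; no
discounting, currency conversion or indirect costs. The history/fish tier
weights are those of one mildly iodine-deficient area and need not transfer.
The allocation reproduces published aggregates exactly but the joint
distribution of flags within strata is only constrained at the
tier × outcome level; per-woman flag assignments are one of many
aggregate-consistent configurations, chosen deterministically.
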