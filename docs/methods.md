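# Methods

## Scope and model

The package analyses cohorts of patients with a germline pathogenic
*BRCA1/2* variant and paired primary/recurrent tumors. Upstream steps —
alignment, variant calling, allele-specific segmentation — are consumed,
not performed: inputs are integer allele-specific copy-number segments
(1-based inclusive coordinates), annotated somatic variant tables,
two-isoform transcript counts, and per-patient survival records.

### LOH calling

Zygosity is a deterministic function of the segment's integer allele
counts: zero minor (B) alleles is LOH, at least one is heterozygous. The
tumor-level call is the zygosity of the unique segment containing the
germline locus (exact point containment, no padding); a locus falling into
a gap between segments yields `indeterminate`. A homozygous deletion (0,0)
also has zero B alleles and is classified LOH but flagged separately,
because both alleles — including the mutant one — are lost; segment data
alone cannot distinguish which allele went first.

Trajectory classification works on timepoint-ordered calls with the primary
first. Indeterminate calls are dropped from all comparisons and can never
flip a label. If the determinate recurrences disagree among themselves the
patient is `mixed`; otherwise concordance or the direction of the single
transition against the primary decides the label. At least two determinate
calls are required. A somatic second hit counts as biallelic inactivation
when a LoF variant in the germline-mutant gene reaches AAF ≥ 0.25 — below
that, too few tumor cells carry the second hit to abolish wild-type
function.

### Scar scores

The scoring thresholds are not free parameters of this package's model;
they are the standard values from the literature in which each component
originated, collected in `ScarConfig` (all in base pairs) and echoed into
output headers:

| parameter | default | meaning |
|---|---|---|
| `hrd_loh_min_len` | 15 Mb | minimum LOH run length (strictly greater) |
| `lst_min_segment` | 10 Mb | minimum flank length at an LST breakpoint |
| `lst_smooth_below` | 3 Mb | segments below this are smoothed away |
| `ntai_min_len` | 1 Mb | minimum allelic-imbalance run length |
| `telomere_tolerance` | 0 bp | slack for "reaches the chromosome end" |

All three HRD components operate on maximal runs of one allele-specific
state (contiguous same-state segments merged first), which makes every
score invariant under splitting a segment into same-state pieces. LST
additionally merges same-state neighbours across gaps below the smoothing
threshold, then iteratively removes the shortest sub-threshold run
(leftmost on ties) and re-merges flanks, and finally counts state changes
where both flanks are ≥ 10 Mb with a gap < 3 Mb. "Crossing the centromere"
for NtAI means any overlap with the annotated centromere interval.

The aneuploidy score counts chromosome arms on which at least 80% of the
arm length carries a total copy number different from the sample's ploidy
rounded to the nearest integer (ties up). The 80% rule makes the score a
whole-arm statistic robust to focal events. TMB is the exact quotient of
filtered exonic nonsynonymous SNVs + indels (synonymous calls excluded)
over the capture size in Mbp.

Paired primary/recurrent score comparisons use two-sided Wilcoxon
signed-rank tests with the Pratt zero-handling; for patients with several
recurrences one is chosen by a seeded RNG and the chosen pairing is
returned alongside the p-values so reports are reproducible. All-zero
difference vectors return p = 1 by convention; a single pair yields the
trivial exact p rather than an error.

### Copy-number annotation and segment-set comparison

Total copy number bins as 0 = Deletion, 1 = Loss, 2–3 = Neutral, 4–5 =
Gain, ≥ 6 = Amplification. A gene's copy number is the minimum over the
covered parts of its locus; uncovered basepairs contribute to no category,
and the covered fraction is exposed so poorly covered genes can be
filtered. Deletion requires > 50% of the locus in Deletion-binned segments;
amplification requires 100% coverage by Amplification-binned segments —
an asymmetry that reflects how much more localized amplicons are.

Two interval sets are compared at 50% reciprocal overlap: a pair is a
candidate match when the intersection covers at least half of *each*
interval, matching is greedy by overlap length (deterministic on ties), and
unmatched segments are private to their set. The Jaccard statistic is
basepair-based on the merged footprints (intersection length over union
length), independent of the matching. The minimal common region is found by
a breakpoint sweep over per-sample merged intervals: elementary intervals
between consecutive breakpoints carry a support count (number of samples
covering), and the leftmost contiguous run of maximal support is reported
with its support.

### Somatic variants

The filter keeps exonic variants passing at least one caller, with alt
depth ≥ 5 and PopFreqMax < 0.01; an absent population frequency is kept
(treated as rare) and an absent REVEL score makes a missense variant
non-LoF — both choices are conservative in opposite directions and are
logged per variant. LoF/GoF classification is a pure function of the
variant plus two local lookup tables; the shipped tables are small
*synthetic stand-ins* for the licensed COSMIC/CGC releases (same schema,
documented in `somatic_variants.load_cosmic_set`/`load_cgc_table`), so
users must substitute real releases for production use. Prevalence
rankings count each gene at most once per patient per tumor group and break
ties lexicographically, giving byte-stable `.rnk` files.

### Isoform usage and survival

With two transcripts the isoform fraction IF_short = short/(short+long).
Dominance uses a single threshold: a sample expresses "both" isoforms when
the minor IF ≥ 0.2, otherwise the majority isoform dominates; zero total
expression is "none" and the IF undefined. The 0.2 default makes
mutual-exclusivity tables computable from count data without an expression
floor. Patient exposure is monotone: any short- or both-dominant tumor
exposes the patient.

The differential-usage test is deliberately simpler than an exon-level GLM:
a two-sided rank-sum test on per-sample IF_short with Benjamini–Hochberg
across tested genes and an effect gate |dIF| ≥ 0.1. This trades the
count-level dispersion model for transparency; with only two isoforms of
one gene the IF is a sufficient per-sample summary, but very low counts
make IF noisy — a caveat inherited by every downstream call.

The Mantel–Haenszel trend statistic is implemented in closed form with the
hypergeometric (n−1) variance and a 0.5 continuity correction — the same
form R's `mantelhaen.test` computes (the test suite cross-checks against
statsmodels). With a single stratum this equals the Yates-corrected
chi-square times (n−1)/n; the factor is the finite-population correction
and vanishes with n.

Cox models are fitted by partial likelihood with the Efron tie
approximation (via lifelines); confidence intervals are exp(coef ± 1.96·SE)
and per-term p-values are Wald tests. Covariates are an explicit
specification, never stepwise selection: the breast analysis is univariate
exposure; the ovarian analysis adds recurrent status. KM medians report
inf (open-ended) when the survival curve never crosses 0.5 and require at
least two events per arm.

## The synthetic cohort

The generator emulates the study's inputs with full ground truth. Design
choices that matter:

- **Diploid background.** Outside injected events every basepair is (1,1),
  so scores have no background contribution and the injected counts are
  exact oracles.
- **Buffered events.** Each event is shouldered by 4 Mb segments — above
  the smoothing threshold but below the LST flank minimum — so no event
  boundary can qualify as a large-scale transition unless it was designed
  to. NtAI events are 8 Mb telomeric (2,1) blocks; HRD-LOH events are
  18 Mb interstitial (2,0) cores (total copy 2, invisible to the
  aneuploidy score); LST events are chains of alternating balanced ≥ 11 Mb
  blocks behind one shoulder, each chain of m blocks contributing exactly m
  qualifying breakpoints; arm events cover > 80% of an arm with balanced
  off-ploidy states. The germline-locus LOH block is a 10 Mb (1,0) core —
  long enough to contain the locus, short enough never to count as
  HRD-LOH.
- **≥ 5 Mb spacing** between events prevents merging/smoothing from fusing
  them; every injection is re-scored internally and a mismatch is a hard
  error.
- **Genome presets.** The default `toy` genome (3 chromosomes, 200 Mb)
  keeps test cohorts fast and caps injectable events at small counts; the
  `medium` preset (8 × 160 Mb, 16 arms) hosts up to ~10 events of each
  class per sample and is used for the recovery experiments. Capacity is
  checked before any file is written.
- **Cohort structure.** Primaries are LOH with probability 0.8 (matching
  the ~80% LOH prevalence the cohort design targets); recurrences follow a
  two-state Markov chain with 0.1 transition probabilities in each
  direction, producing mostly concordant pairs with occasional gains and
  reversals. Clonal variants are shared across a patient's tumors at AAF ≈
  purity/2 (heterozygous, diploid locus); private variants are subclonal
  (20–60% of clonal AAF); ~80% of patients carry a clonal TP53 LoF driver.
  Decoy variants failing exactly one filter rule exercise the filter.
  Isoform dominance is drawn per group (10% / 25% / 60% short-dominant for
  normal / primary / recurrent) with 97% mutual exclusivity. Survival
  times are exponential with baseline hazard 0.01/month and a true hazard
  ratio of 2.5 for exposed patients, under independent exponential
  censoring calibrated to a 20% baseline censored fraction.
- **Determinism.** A single seed spawns five independent component streams
  (structure, scars, variants, isoforms, survival), so the same seed gives
  byte-identical cohorts and changing one model block leaves the others'
  draws untouched.

What the generator does *not* emulate — read-level noise, segmentation
error, non-integer (subclonal) copy number, trinucleotide mutation
contexts, transcript quantification uncertainty — bounds what green tests
mean: they validate the scoring/calling logic exactly, not robustness to
upstream estimation error. With integer allele-specific input, LOH recovery
is exact at any purity; on real data the purity enters upstream, in the
segmentation.

## Verification

The test suite checks, among others: exact recovery of injected scar
counts (50 samples, counts to 10 per class, on the medium genome);
agreement of all interval logic with independent quadratic/per-basepair
enumerators on 1,000+ random profiles; 100% trajectory recovery on 200
planted patients; boundary exactness of every filter threshold; Cox CI
coverage ≥ 93% over 200 replicates at n = 500 with a true HR of 2.5 and KS
uniformity of the null Wald p over 500 replicates at n = 200; and the MH
statistic against a frozen R `mantelhaen.test` value. Problem sizes were
chosen so the full suite runs in a few minutes on one core. The one
real-data check — reproducing the published breast-cancer survival
analysis (HR 2.535, medians 87 vs 121 months) — requires the study's
protected per-patient supplementary table and fails with an explanatory
message when that file is absent.

## Known limitations

- Segment-level input only: no BAF/read-level evidence, so an LOH call is
  only as good as the upstream segmentation.
- The shipped COSMIC/CGC tables are synthetic stand-ins; GoF calls on real
  data require the licensed releases.
- The usage test is not a dispersion-aware GLM; with shallow transcript
  counts its IF estimates are noisy.
- The aneuploidy definition (arm count vs rounded ploidy at 80% coverage)
  is one of several in circulation; compare scores across cohorts only
  under the same definition.
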