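# Methods

## Problem setting

A sudden-death-in-the-young (SDY) cohort study compares decedent
genomes against a living, sex- and ancestry-matched reference cohort,
asking three questions: (i) are genes from curated epilepsy and
cardiomyopathy/arrhythmia (CMAR) panels carrying damaging variation
more often than random gene sets, and more often in cases than
controls; (ii) does the per-decedent burden of rare panel variants
predict age at death; (iii) which panel genes harbour more rare
variants of uncertain significance (VUS) than their share of reference
variation predicts. The real genomes behind such studies are
controlled-access, so the package pairs the statistical machinery with
a synthetic cohort generator that reproduces the structure the analyses
assume and lets effects be planted at known sizes.

## Damaged-gene enrichment

Damage evidence arrives as a per-(sample, gene) score on a log10
Bayes-factor-like scale from an upstream AI prioritiser; the score is
an input, never recomputed here. A (sample, gene) pair is *damaged*
when its score is at or above 0.69, the prioritiser's published
operating point; a gene is damaged *in an arm* when any sample of the
arm damages it (maximum aggregation — one qualifying call marks the
gene, matching how gene lists are intersected with a cohort-level
damaged-gene list).

For a gene list of size N the observed statistic is the number of its
genes damaged in the arm. The null resamples B uniform random size-N
gene sets (without replacement within a draw, independent across draws)
from the background universe (18,876 genes at study scale) and
intersects each with the arm's damaged gene set. We report:

* the upper-tail, add-one empirical p-value
  (1 + #{draws ≥ obs}) / (B + 1), bounded below by 1/(B+1) so finite
  resampling never produces p = 0;
* the Z-score (obs − null mean)/null SD, which makes panels of
  different sizes comparable; undefined (reported as NaN, never ±inf)
  when the null SD is 0;
* a two-sided Fisher exact test on the damaged / not-damaged × case /
  control 2×2 table (scipy), answering the between-arm question
  directly;
* Benjamini–Hochberg FDR across the gene lists evaluated in a run,
  applied to the case-arm empirical p-values (Bonferroni available).

Both the per-arm empirical p and the Fisher p are always reported
because they answer different questions (absolute excess over random
gene sets vs differential burden between arms); collapsing them into a
single number would discard one of the two. Housekeeping and
burden-matched control gene lists are evaluated through the identical
path as the test panels.

Resampling is vectorised with a random-key trick: a row of U uniform
keys is drawn per gene set and the N smallest keys' positions form the
draw; rows are chunked so the key matrix stays under ~2×10⁷ elements.

## Burden-matched control gene lists

Each universe gene carries a burden ratio: its count of
reference-population rare variants (MAF ≤ 0.005, inclusive) in the
largest coding transcript, divided by the transcript length in bases.
A matched control list for a panel is found by rejection sampling:
uniform random gene sets of the panel's size from the universe minus
the panel, accepted when both the mean and the SD (sample SD, ddof = 1)
of the burden ratio fall within a relative tolerance of the panel's
(default 10%, attempt budget 100,000 — both configurable; the source
procedure states only "randomly sampling", so rejection sampling is the
simplest consistent reading). A failed budget raises an error carrying
the best candidate and its deviations; an optional greedy single-gene
swap refinement serves tolerances too tight for rejection alone. Note
that matching by first acceptance shrinks the achieved mean slightly
toward the universe mean within the tolerance window; over random
targets the shrinkage is symmetric and cancels (tested).

## Age-at-death burden regression

Per-decedent counts of nonsynonymous panel variants are tabulated over
five global allele-frequency bins with edges (0.001, 0.01, 0.1, 0.25,
0.5). Every internal edge is strict (af < edge falls below it), the
final bin is closed at 0.5, and frequencies above 0.5 map to an
overflow label excluded from analysis — the bin notation "<0.001"
appears consistently in the source presentation, so strict-< is the
default everywhere, including the rarity threshold (< 0.001) shared by
the burden and VUS analyses; all edges are configurable.

Each bin's count is the covariate in an OLS fit of age at death (years)
on burden plus ancestry PCs 1–6, cases only (the reference cohort has
no age). The slope is in years per additional variant — the raw count
is deliberately not standardised. Raw two-sided slope p-values are FDR
adjusted across the bins (the adjustment method in the source is
unstated; BH is used for internal consistency with the enrichment
stage, Bonferroni is available). Fits are refused rather than silently
degraded on: zero-variance response, zero-variance covariate,
rank-deficient design (the most collinear pair is named), or fewer
complete cases than covariates + 3; listwise deletion counts are
logged.

The extreme-value sensitivity analysis refits after dropping every
carrier of the minimum and of the maximum rare-bin burden value (a
percentile rule is available); both fits are always reported side by
side with the exclusion count, so the trimming rule — unstated in the
source — is transparent. Subgroup burden comparisons (e.g. epilepsy-
vs cardiac-cause decedents) use a two-sided Wilcoxon rank-sum test:
exhaustive enumeration over all group assignments with midranks when
both groups have ≤ 10 members, tie-corrected normal approximation
otherwise, with the method reported alongside the p-value.

## VUS observed-vs-expected model

A VUS here is a rare (af < 0.001) nonsynonymous cohort variant whose
ClinVar class is none of {P, LP, B, LB}; a *suspicious* VUS
additionally has M-CAP strictly above 0.025 (a missing M-CAP score is
never suspicious, and is logged). Per-gene expected counts follow a
multinomial model: gene g's probability is its reference variant count
divided by the gene-set total, times the cohort's total observed count
— so Σ expected = Σ observed by construction. Genes are ranked by
descending excess (observed − expected); ties are broken by descending
suspicious count, then lexical symbol, making the ranking a total
order. "Approximately equal" excess is exact equality by default (a
configurable absolute tolerance groups near-ties), chosen so near-ties
are never silently reordered. The nonsynonymous filter is shared with
the burden analysis; a missense-only switch exists because the source
alternates between the two terms in this analysis.

## Ancestry principal components

Allele dosages (0/1/2, missing allowed) are centered per variant at
2p and scaled by √(2p(1−p)) with p the observed allele frequency — the
population-genetics standard when only "SVD" is specified; unit-SD
scaling is a switch. Missing dosages are mean-imputed (zero after
centering), monomorphic variants are dropped with a log entry, and the
top-k left singular vectors scaled by their singular values are the PC
coordinates. The sign of each component is fixed by making its
largest-magnitude variant loading positive, so results are reproducible
and invariant to variant order. Requesting more components than the
matrix rank fails with the achievable rank. Explained-variance
fractions are squared-singular-value shares.

## Synthetic cohort generator

`SimulationConfig` defaults reproduce the motivating study's scale: an
18,876-gene universe, 211 cases + 211 controls, panels of 191/118/82/
143 genes with the smaller epilepsy and cardiac panels overlapping the
larger ones, and null effects (enrichment_effect = 1,
age_effect_slope = 0).

What it emulates:

* transcript lengths log-normal (median ≈ 2.4 kb), per-gene reference
  rare-variant rates gamma-distributed (mean 0.05/base, shape 2), so
  burden ratios are heterogeneous and matched sampling is non-trivial;
* per-sample variant counts Poisson (0.02 expected nonsynonymous and
  0.01 synonymous variants per sample per gene, chosen for test power —
  the source reports no per-sample panel-variant summaries), allele
  frequencies from a site-frequency-spectrum-shaped five-bin mixture
  (weights 0.50/0.20/0.15/0.10/0.05, log-uniform within bins);
* damage calls generated per (sample, gene) directly — the upstream
  damage caller is a black box whose thresholded output is all the
  analysis consumes — at null probability 0.002 per pair, multiplied by
  `enrichment_effect` for case-arm panel genes (clipped at 1), with
  above-threshold scores threshold + Exponential(0.5) and an equal
  number of sub-threshold background calls exercising the cutoff;
* case ages: intercept 5 y + slope × (rare panel-variant count) +
  N(0, 4 y), truncated at 0, with a warning when truncation exceeds
  half the arm; controls carry no age;
* ancestry as 3 latent clusters (weights 0.45/0.30/0.25) separated by
  5 units in the PC1–PC2 plane with unit noise; stored PCs are the
  cluster coordinates plus noise, not re-derived by SVD, unless the
  ancestry module is invoked explicitly;
* the control arm exactly replicates the case arm's joint sex ×
  cluster composition (a permutation when sizes match), and sex (61%
  male) has no effect on variant generation — it exists to exercise
  matching.

What it does not emulate: linkage disequilibrium, per-gene mutational
targets coupled to transcript length in the cohort arm, pedigree
structure, sequencing error, or the correlation between damage scores
and variant annotations. Passing tests therefore demonstrate that the
statistics are correct and calibrated under the assumed generative
structure, not that real cohorts satisfy that structure.

## Problem sizes used by the test and acceptance runs

Property experiments run at reduced scale, chosen once: null
calibration uses 200 studies of 600 genes and 100+100 samples with a
60-gene panel at B = 10,000 (3-binomial-SE band around the nominal 5%
rejection rate; the discrete add-one empirical p is super-uniform, so
its rate may sit slightly below nominal but not above); planted-effect
recovery uses 40 studies of 1,000 genes and 200+200 samples with a
100-gene panel, enrichment_effect = 3 and age_effect_slope = −0.5;
oracle agreement enumerates all 2×2 tables with margins ≤ 15 and uses
B = 50,000 on a 20-gene universe; the multinomial goodness-of-fit check
draws 200 cohorts of 2,000 variants over ~40 genes. Default B for real
runs remains 100,000.

## Known limitations

* The VCF dialect stores frequencies and scores as standard Float INFO
  fields, i.e. 32-bit: a round trip preserves them to ~7 significant
  digits, while the TSV dialect round-trips exactly.
* No compound-heterozygosity phasing: zygosity is taken from the input
  record, and heterozygous P/LP hits in recessive-inheritance genes
  (default list QARS, CLN8, PPT1, CSTB, FKRP) are flagged as likely
  incidental but retained.
* ACMG vs ClinVar precedence: a variant counts as P/LP when either
  source says so, since published variant tables mix both evidence
  streams; cohort-level summaries report raw counts so either
  percentage rounding convention can be applied downstream.
* Global allele frequency drives every analysis by default;
  ancestry-specific frequency is carried through but unused unless
  switched on, as the rarity criteria in the source cite global
  frequencies.
* No ACMG criteria engine, no annotation (consequence classes,
  ClinVar/ACMG classes, M-CAP and damage scores are inputs), no CNV
  handling, and no survival modelling — age at death is a continuous
  response.
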