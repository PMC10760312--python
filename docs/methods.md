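# Methods

## The statistic

The unit of analysis is the per-individual homozygosity rate: homozygous
non-reference calls divided by non-missing genotyped loci over an eligible
variant set. Three conventions matter and are fixed in `io_model`:

* Calls count non-reference alleles (0/1/2, −1 for missing); "homozygous"
  means call = 2 — homozygous *reference* calls never enter the numerator.
  Missing calls leave both numerator and denominator, so denominators differ
  between individuals; a sample with no genotyped eligible locus gets NA
  (propagated, never zero-filled), so downstream tests drop such samples
  explicitly.
* Allele frequencies come from population annotation, not from the cohort:
  the genome-sequencing track first, the exome track as fallback, and 0.0
  for non-reported variants (which therefore land in the ultra-rare
  stratum). Strata: common ⇔ AF ≥ 0.01 (the boundary is inclusive), rare
  ⇔ AF < 0.01, ultra-rare ⇔ AF < 10⁻⁴ (a subset of rare; common and rare
  partition all variants).
* Variant positions are 1-based; BED intervals 0-based half-open, so a
  variant at position p is inside (start, end] iff start < p ≤ end. Gene-set
  membership is by annotated symbol equality (case-sensitive after
  trimming), not coordinates.

## Quality control

Three stages, mirroring standard array QC: (1) pre-stage variant filters —
call rate < 98% or exact Hardy–Weinberg p ≤ 0.001; (2) sample filters —
missingness > 3%, heterozygosity rate at least 3 sample SDs from the cohort
mean (two-sided; with SD = 0 nobody is removed — the degenerate
"0 ≥ 0 removes everyone" reading is rejected), and an injectable
sex-discordance predicate, since sex-chromosome markers are outside the
modeled array; (3) a final variant missingness filter (> 5%) with the
post-sample-QC denominator. The call-rate and missingness filters overlap
deliberately: they are distinct passes with pre- and post-sample-QC
denominators.

The HWE test is the exact conditional test: given the allele counts, the
heterozygote count is enumerated over its parity-constrained support with
log-gamma weights, and the two-sided p sums the probabilities of all
configurations no more likely than the observed one (relative tolerance
1e-12 on the comparison). The unit tests check it against an independently
constructed oracle that builds the same distribution by the mid-support
recurrence, over every genotype table with at most 200 alleles.

## Burden tests

*Routing.* The overall burden test uses Student's t (pooled variance) only
when **both** groups pass the D'Agostino–Pearson omnibus normality test at
α = 0.05 and both have n ≥ 8 (the omnibus test's validity floor); otherwise
Mann–Whitney, exact when both groups are ≤ 20 without ties, else the normal
approximation with tie and continuity corrections. Requiring both groups to
pass is the conservative reading of "normally distributed data".
Benjamini–Hochberg adjustment is applied within one comparison family = the
panel of contexts tested together for one contrast, not across contrasts.

*Relative burden.* Both groups are pooled; the threshold is pooled mean +
1 sample SD (ddof = 1); "high burden" is strictly above the threshold. The
2×2 of high-burden × group goes to the exact engine. A pooled SD of 0 gives
a degenerate result (p = 1, OR = 1, flagged) rather than an error.

## Exact 2×2 inference

All three quantities condition on both margins. The two-sided Fisher p uses
probability ordering with relative tolerance 1e-7 on the ≤ comparison,
matching the convention of widely used implementations. The odds ratio is
the **conditional MLE** (root of the conditional score equation
E_ψ[X] = a, solved by bracketed bisection in log ψ), not the sample
cross-product ratio, and the confidence bounds are exact tail inversions
(P_ψ(X ≥ a) = α/2 for the lower bound, root-finding tolerance 1e-8 in ψ).
This construction was chosen because it reproduces the published zero-cell
rows — carriers only in the case group give OR = ∞ with finite exact lower
bounds 1.30 (3/117 vs 0/259) and 1.32 (2/57 vs 0/259) at 90% confidence,
the strongest available cross-calibration against the R routine used for
the original tables. Support weights are computed in log space, safe for
margins up to ~10⁵. Default confidence is 0.90 throughout for consistency.

## Collapsing analysis

Primary filter: homozygous calls at common variants whose consequence is
exonic or splice-relevant intronic (multi-consequence annotations collapse
to the most severe category under exonic > intronic-splice > intronic-other
> other > intergenic). Secondary filter: SIFT < 0.05 **or** PolyPhen > 0.9 —
"and/or" is read as disjunction (the permissive literal reading; a
conjunctive mode is available behind `and_mode=True`); absent scores satisfy
neither arm. Carrier indicators are binary per gene (≥ 1 qualifying
variant); variants annotated to multiple '|'-separated genes count toward
each, which cannot double-count within a gene. Genes are tested case group
versus comparison group with the exact engine; "suggestive" means unadjusted
p < 0.05 (BH-adjusted values are emitted for transparency but not
thresholded). The comparison group for both NDD and ASD contrasts is the
non-NDD pool. Carrier percentages are reported over the tested group's true
n.

## Phenotype prediction

Backward stepwise selection on AIC over the context burdens: start
saturated, evaluate every single-predictor removal, accept the removal with
the lowest AIC if it improves on the current model, stop otherwise. Ties
break by predictor name order, making selection deterministic. Sex enters
only *after* selection (an unusual but deliberate design, preserved as
such), and is omitted entirely for the case-only-versus-cancer contrasts
whose sex skews are opposed. Validation: stratified 80/20 split (the data
are ~15–30% positive at n ≈ 300–400, so unstratified splits risk degenerate
folds), selection on the training split (full-data selection available via
`select_on="full"`), 10-fold stratified CV on the training portion for a
fold-mean accuracy, and hold-out accuracy (threshold 0.5) plus trapezoidal
ROC/AUC as headline metrics — both are printed and labeled, since either
could be the figure of merit. Perfect separation or non-convergence in a
maximum-likelihood fit triggers a refit with a tiny ridge penalty
(λ = 10⁻⁶), flagged in the report.

## The synthetic cohort

No genotype data are distributable for the modeled study, so the generator
is a first-class module defining the study conditions: 376 individuals —
117 NDD (57 ASD; 14 cancer-comorbid, 3 of them ASD), 175 cancer, 84 other —
with the published per-group sex ratios (69/74/18/54% male) and
variant-classification mixes; biallelic autosomal genotypes drawn
independently per sample under HWE with allele frequencies from a mixture
spectrum (default 60% common uniform on [0.01, 0.5], 30% rare on
[10⁻⁴, 0.01], 10% ultra-rare below 10⁻⁴); and uniform missingness (default
0.2%). The default 20,000 variants stand in for a full array at desk scale;
all rate statistics are per-locus averages, so context-level behaviour is
governed by variants *per context*, which matches the batteries (200-variant
contexts). Planted effects:

* context inflation adds δ to the hom-alt probability (heterozygote mass
  reduced) for one group's samples at one context's variants; planted
  contexts are forced common so the heterozygote mass can support δ (the
  generator rejects infeasible δ). An inbreeding-style mode
  (P(hom-alt) = q² + F·q(1−q)) is available for realism. Effects are
  parameterized on the hom-alt probability directly because that is what
  the statistic counts.
* qualifying-variant planting makes one common (q = 0.1), exonic,
  SIFT-deleterious variant homozygous in exactly n designated carriers of
  one group and het/ref everywhere else, with the gene's remaining variants
  forced non-qualifying — the clean infinite-OR pattern. Planting happens
  after missingness so carrier counts are exact.

Annotations expose the true simulated frequency (optionally perturbed), so
MAF stratification in tests is exact. The generator does **not** emulate
linkage disequilibrium, realistic chromosome maps, relatedness, population
structure, or annotation error; passing tests therefore demonstrate the
pipeline's statistical behaviour under idealized independence, not
robustness to those features of real data.

## Problem sizes and numerical choices

The test batteries run at the sizes the properties are stated for: the HWE
oracle sweep covers every table with ≤ 200 alleles; type-I calibration uses
500 null contexts (binomial 99% band around 0.05); power uses δ = 0.05 over
200-variant contexts at 117 vs 259 samples, 200 replicates (> 80%
rejection); carrier-gene recovery uses 100 planted and 100 null replicates.
The analysis drivers default to 20,000 variants and finish in well under a
minute end to end. Degenerate inputs resolve explicitly rather than
silently: empty contexts → NA profiles; constant pooled rates → degenerate
relative-burden result; empty conditional support → OR 1 with a degenerate
flag; monomorphic sites → HWE p = 1.

## Known limitations

Backward stepwise selection is greedy; equality with exhaustive best-subset
search is asserted only on fixtures without masking structure. The staged
QC design is idempotent on realistic data but not provably so in adversarial
cases (sample removal changes variant-level denominators and HWE p-values).
Running consequence/deleteriousness annotation tools, pathway enrichment,
ancestry PCA, relatedness pruning, and run-of-homozygosity segment detection
are out of scope; the pipeline consumes pre-made annotation tables, and the
statistic is per-SNP, not segmental.
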