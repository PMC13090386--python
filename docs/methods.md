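# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why, the synthetic-data generator's planting model, and the
numerical choices that affect results.

## Coordinates and input handling

All internal coordinates are 0-based half-open; VCF positions are converted
on read, BED-family inputs are native. Indels occupy their reference
footprint `[pos, pos + len(ref))` and overlap regions by that footprint.
Multi-allelic records are rejected by default (`multiallelic="reject"`,
with a skip counter) or split into per-allele records; rare variants are
expected heterozygous but homozygous carriers are treated as carriers
(dosage ≥ 1). MAF is taken from `INFO/MAF` when present, else computed as
alt-allele count over 2N cohort alleles.

## Interaction QC

Kept iff: supporting pairs ≥ 5, Bonferroni-adjusted p < 0.05, cis,
anchor-midpoint distance < 5 Mb, both fragment lengths < 7500 bp. The
boundary semantics mirror the filter definitions exactly (support keeps at
the boundary; distance and fragment length drop at the boundary). Whether
the 5 Mb cut applies to midpoints or nearest edges is not specified
upstream; midpoints are used. Dropped interactions are attributed to the
first failing rule in the fixed order support → p → trans → distance →
fragment, so per-rule counts partition the removed set; this ordering is a
reporting convention only.

## Event classification

The cohort splits into carriers C and non-carriers N for each rare variant
(MAF < 10%). For each QC-passing interaction overlapping the variant at
either anchor, presence P is the patient set in which the interaction was
observed. Concordance uses **subset semantics**: P ⊆ C is concordant GoI,
P ⊆ N concordant LoI, anything spanning both classes is discordant. Strict
equality semantics (P = C or P = N) is available via
`concordance="equality"`; subset semantics is the default because rewiring
"exclusively in carriers" does not require every carrier to show the
contact (capture sensitivity varies per library). Discordant direction is
the majority presence rate with ties to GoI; it decorates optional columns
only. Variants with no carriers or with all patients as carriers provide no
genotype contrast and yield no event. Events are counted per
(variant × interaction) pair and per overlapped component, so a variant
hitting both anchors contributes one promoter event and one enhancer event.

Odds ratios are sample cross-product ratios ad/bc (not the conditional
MLE); this convention reproduces the published worked-example values
exactly. Two-sided Fisher p-values use the hypergeometric
point-probability rule (scipy).

## Motif impact

PWM scores are additive log-odds. Score distributions are computed on a
fixed-point grid of step 1e-4 (weights rounded once to the grid; scoring
uses the grid weights), and the null distribution over background words is
obtained by exact per-position convolution of integer score offsets. This
makes p-values reproducible independent of floating-point summation order;
the survival function is exact for the discretized matrix, and agreement
with exhaustive 4^L enumeration is at the 1e-13 level (asserted ≤ 1e-9 in
tests). A variant's p_ref/p_alt are best-hit p-values over all placements
covering the variant base, both strands by default; impact =
log₂(p_ref/p_alt). Calls require a valid hit (p ≤ 0.0005, the annotation
tool's default threshold, kept verbatim) on the gaining side plus a
fold-change of ≥ fc_min = 2 in log₂ units (4-fold, the conventional
default; configurable — no cutoff is stated upstream). Count matrices are
converted to log-odds with pseudocount 1 distributed by background
frequency. Indels are supported as an extension by scoring equal-length
flanked ref/alt windows.

## Allelic imbalance

The upstream beta negative binomial model with adaptive coverage filters
is replaced by a **beta-binomial conditional-on-total** model: given
n = ref + alt reads at a heterozygous site, alt ~ BetaBin(n, ½, ρ) under
the null, with a single global overdispersion ρ estimated by method of
moments from the across-site variance of alt fractions (clipped to
[0, 0.5]; ρ = 0 with a warning below 20 sites). The conditional model
captures the same allelic-ratio null at package scale and is exactly
testable against Monte-Carlo; results are not claimed to equal the original
tool's. At ρ = 0 the test reduces to the exact binomial test. One-tailed
p-values include the observed point mass; the minimal one is doubled and
capped at 1. Count QC keeps sites with GQ ≥ 50, DP ≥ 10 and ≥ 5 reads per
allele (all inclusive).

Gene-level aggregation is two-stage: per gene and individual, SNV p-values
are combined with the Mudholkar–George logit method
(T = −Σ ln(pᵢ/(1−pᵢ)), referred to c·t with ν = 5k+4 and
c = √(kπ²(ν−2)/3ν)); per-individual gene p-values are re-combined across
individuals the same way; BH runs across genes. A single p-value is passed
through unchanged.

**Degenerate p-values.** The doubled-and-capped discrete statistic has a
large point mass at exactly 1 (any near-balanced site). Clamping p = 1 at
the float boundary before the logit transform (logit ≈ 36.7) would let one
balanced site cancel several strongly imbalanced ones — in simulation this
systematically degraded planted-gene ranking. p = 1 is therefore clamped at
1 − 1e-4 (logit ≈ 9.2), which is still conservative relative to a
mid-p-style discrete correction (the point mass would map p = 1 to roughly
1 − mass/2); p = 0 is clamped at 1e-300. Both emit a warning.

A second genuine attenuation is documented rather than patched: the
≥ 5-reads-per-allele QC preferentially removes the *most* imbalanced sites
of a truly imbalanced gene (at alt fraction 0.8 and depth ~60, the minor
allele often falls below 5), biasing surviving sites toward balance. This
is faithful to the upstream filter and explains occasional low planted-gene
ranks in simulation.

## Cell-type enrichment

MAF strata are half-open: MAFa [0, 2%), MAFb [2%, 4%), MAFc [4%, 10%). The
top stratum's nominal "5%" label is internally inconsistent with 2%-wide
lower strata under a 10% cohort cap; [4%, 10%) keeps the strata contiguous
and exhaustive (boundary configurable). "Expressed" means mean expression
> 0 in the cell type by default (no cutoff is stated upstream; the floor is
configurable). The proportion denominator is the expressed (optionally
DE-flagged) gene universe of the cell type — an explicit configuration
choice recorded in results. Test 1 compares altered-gene proportions
between cohorts for promoter concordant events; test 2 does the same for
enhancer events, separately for concordant and discordant classes. BH
families run across cell types within each (stratum × component × class),
matching a per-test FDR presentation; the promoter-test significance is
conventionally read at p < 0.1 and the enhancer tests at FDR < 0.05, both
exposed as thresholds. DE flags come from a two-sided Wilcoxon rank-sum
test of each cell type against the pooled rest with BH q < 0.05 and a
higher in-group median. Network summaries report 2|E|/|V| to 2 decimals
over deduplicated unordered edges.

## Synthetic cohort generator

The generator emulates the targeted study design: 8 cases + 8 controls,
heterozygous rare variants over the three MAF strata (default mix
50/30/20%), patient-specific interaction sets, overdispersed allelic
counts, and log-normal expression. A single root seed spawns independent
substreams per stage so stages regenerate in isolation; the same seed
yields byte-identical output files. The genome is one abstract chromosome
with disjoint promoter (800 bp, one gene each) and enhancer (600 bp)
intervals; all generated interactions satisfy the QC thresholds by
construction.

Planting model:

* **Events.** Each planted event gets a dedicated promoter–enhancer pair
  that background interactions never reuse; presence is set to the carrier
  set (GoI), its complement (LoI), or a mix (discordant). Background
  interactions are present in *every* patient, which always classifies as
  discordant — so in the noiseless setting (presence_noise = 0) no chance
  concordant event can arise and planted labels are recoverable exactly.
  Defaults: 50 concordant GoI, 20 concordant LoI, 30 discordant; carriers
  1–3 patients within one cohort (so events are cohort-specific);
  components and cohorts alternate.
* **Allelic counts.** 5 imbalanced genes (alt fraction 0.8) and 200 null
  genes, 5 SNVs × 4 patients each, depth ~ Poisson(60), ρ = 0.1.
* **Expression and burden.** Per-gene per-cell-type expression is on/off
  (probability 0.3) with log-normal means; 20 DE genes per cell type at
  2-fold effect, with per-cell matrices for the rank-sum flagger. The
  planted cell-type burden is a symmetric case/control expression-odds
  contrast in the target cell type: case concordant-event genes are
  expressed there with probability min(1, 0.3·odds) and control event
  genes with 0.3/odds. The default odds of 10 makes the planted burden
  essentially deterministic — the generator's job is recoverable ground
  truth, and weaker planting left recovery at the mercy of Fisher-test
  noise on the ~8 event genes a stratum holds; odds = 1 is the exact null
  used for calibration replicates.
* **Motifs.** Each planted variant is annotated with one TF (round-robin
  over 20 TFs in 5 families, GoM for GoI and LoM for LoI); background
  variants get random annotations, optionally with a case-biased family
  (default FAM1 at 3× odds) to exercise the family-burden test.

What the generator does **not** emulate: linkage disequilibrium, read-level
noise, reference-mapping bias, per-library capture efficiency differences,
contact-frequency fine-tuning, or realistic expression covariance. Passing
recovery tests therefore demonstrates correctness of the pipeline's logic
and calibration under its model assumptions, not performance on real
capture Hi-C data.

## Problem sizes and runtime choices

The default simulated cohort (16 patients, 500 genes, 1500 enhancers, 2000
variants) generates in ~1.5 s and runs the full pipeline in under a minute.
Calibration checks use 10⁴ beta-binomial null draws (depths 20–200,
ρ = 0.05) for the imbalance test and 500 reduced-size null cohorts
(60 genes, 150 enhancers, 60 variants, 5 cell types, burden odds 1) for the
enrichment false-discovery rate; PWM p-values are verified against
exhaustive enumeration for 100 random matrices of length ≤ 8. These sizes
were chosen to characterize behaviour thoroughly at desk scale.

## Known limitations

* The beta-binomial substitute shares only its null hypothesis with the
  original beta-negative-binomial tool; effect-size estimates differ.
* Fisher tests on small per-stratum gene counts have limited power; the
  enrichment stage reports tables alongside p/q so users can judge counts.
* The discrete doubled imbalance p-value is conservative (measured type-I
  ≈ 0.04 at nominal 0.05) and its mass at 1 makes logit combination
  conservative in turn.
* Promoter windows are annotation-defined; the package does not compute
  promoter regions from a TSS set.
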