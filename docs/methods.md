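# Methods

This note documents the models, parameter choices and numerical conventions
behind `utr3qtl`, and what the synthetic-data tests do and do not establish
about real data.

## Variant origin model

The genotype matrix codes each (variant, sample) cell as dosage 0/1/2,
`NO_COVERAGE` (−1) or `FILTERED` (−2). Dosage 0 is asserted only where the
genotyper covered the site; carrier-count denominators exclude
`NO_COVERAGE` cells, because in RNA-seq the absence of a call at an
unexpressed locus carries no genotype information.

Origin classification is a two-component Bayes update per variant:

- **Prior.** Germline carrier probability 1 − (1 − AF)² from the population
  allele frequency, clipped to [1e−4, 1 − 1e−4]. Variants absent from the
  population resource sit at the floor.
- **Likelihood.** The mean VAF across carrier calls is scored under a
  germline-het Beta(20, 20) (centred at 0.5) versus a subclonal somatic
  Beta(2, 6) (centred at 0.25, mirroring an untyped mix of purity and
  clonality). Both shapes are configuration keys, not estimates: real tumor
  VAF distributions depend on purity and copy number, which the generator
  does not model.
- **Hard evidence.** Presence in a carrier patient's blood call set fixes
  P(germline) = 1. Panel-of-normals membership (≥2 of the matched normals)
  multiplies the germline-side odds by a configurable factor (default ×20)
  rather than forcing the label, since recurrent normal calls may also be
  artifacts.
- **Editing overlap** is an annotation on somatic calls at known
  editing-site positions; such variants keep flowing through the somatic
  stream under the `somatic_editing_overlap` label.

Filters: cells tagged `base_qual`, `map_qual`, `n_ratio` or `slippage`
become `FILTERED`; multi-allelic sites are dropped; variants with fewer
than 5 carriers are dropped (a 5-of-375 rule corresponds to a ≥1.3%
frequency gate). Unknown tags are logged, never fatal.

## QTL engine

Counts are TMM-normalized (reference column by the 75th-percentile rule,
30%/5% double trim, inverse-asymptotic-variance weights, factors rescaled
to geometric mean 1) and expressed as counts-per-million of the effective
library size. Genes need ≥1 read in ≥80% of samples. Phenotypes enter the
model through the inverse normal transform Φ⁻¹((rank − 0.5)/n) with
average-rank ties; the 0.5 offset is configurable since conventions differ
at O(1/n).

The association model is OLS of the transformed phenotype on alternative
allele dosage with age, sex, five genotype PCs (Patterson-scaled dosage
SVD, deterministic sign: largest-|entry| coordinate positive) and five
expression surrogate variables. Surrogate variables are the top principal
components of expression residuals after regressing out the known
covariates — a residual-PCA construction; because it does not protect the
genotype signal, dense planted-effect scenarios can shed a little signal
into the SVs (the recovery test therefore plants effects in ≤10% of genes,
matching a realistic sparse-signal regime). Missing dosage is handled by
pairwise-complete deletion; zero-variance dosage yields an `untestable`
flag, not an error.

cis is defined as "within the transcript span", with no flanking window.
Significance is two-stage: BH within each gene's cis family gives per-gene
q-values; eGenes have any q < 0.05; each eGene's nominal threshold is its
largest p with q < 0.05; the horizontal threshold is the median of per-eGene
thresholds taken on log10(p) (even counts give the geometric mean of the
central pair — thresholds span orders of magnitude, so an arithmetic median
would be dominated by the largest one); final calls need q < 0.05 **and**
p below the horizontal threshold. ilQTLs use a per-feature BH family across
all tested variants (the family structure is configurable; per-feature is
the default because immune features are few and heterogeneous).

## Enrichment statistics

The permutation test samples windows uniformly **with replacement** from
the vocabulary of 50-bp 3′-UTR windows (walking step 1); the statistic is
the count of query elements overlapping ≥1 feature, and the empirical p
uses the +1 correction so it never returns 0. Element count was chosen over
base-pair overlap as the statistic. Over-representation is the
hypergeometric upper tail with BH across sets (BH is used throughout; no
Storey estimation). The length-enrichment test is a Pearson goodness-of-fit
of region counts against the regions' share of annotated sequence length.

## MPRA

Oligos are 20-base adapter + 101-base insert + 1-base spacer + 8-base
barcode + 20-base adapter = 150 bases. The insert centres the allele
between 50-base reference flanks; near transcript ends the deficient side
is padded with one shared filler sequence screened against 7–8-base motifs.
Barcodes come from the 4⁸ vocabulary minus forbidden motifs and
homopolymer runs ≥5, sampled without replacement under a seed; ten barcodes
per allele.

Counts are CPM-normalized per sample with a pseudocount of 1 raw count
carried through the scaling; activity is log(RNA/DNA) per barcode per
replicate, quantile-normalized across replicates (reference = across-column
mean of order statistics, ties averaged). Per replicate, alternative vs
reference barcode activities are compared by a two-sided rank-sum test —
exact tie-free enumeration (cached dynamic-programming U distribution) when
both groups have ≤25 barcodes, otherwise the normal approximation with tie
correction. Replicates combine via Stouffer on direction-signed z-scores
(opposite-direction replicates cancel), then BH across variants within each
cell line. Per-allele activity is the median over the allele's
barcode × replicate values; fold change is reported in linear space
(exp of the log-median difference) with a log2 convenience column. The
barcode-level comparison (rather than per-oligo medians) is the default and
a config switch in spirit: medians feed only the effect-size columns.

## ICI cohort and PRS

The synthetic ICI cohort fixes the responder count (default 55 of 135, 45
gastric + 90 melanoma) and draws variant carriage retrospectively: for each
candidate variant, per-class carriage rates are solved by bisection so that
the marginal carriage matches a U(0.05, 0.30) draw and the
carriage–response odds ratio equals the planted value. Under independent
carriage given response this is exactly a logistic model of response on
carriage with coefficients log(OR); the implied per-patient response
probability is recorded as truth. PD-L1 expression is Gaussian with a
responder shift of 0.358 by default (AUC ≈ 0.6, a deliberately weak
baseline).

Selection runs on a stratified half split (68/67 at n = 135): one-sided
Fisher enrichment in responders, BH across candidates, survivors ranked by
Haldane–Anscombe odds ratio (ties: smaller p, then lexicographic id),
optional one-per-gene deduplication, cap 28. "Most highly enriched" is
interpreted as largest corrected odds ratio. The score is the plain count
of signature variants detected in the patient (presence/absence, not
dosage). Evaluation refuses any test set sharing patients with the
signature's training split. ROC points are the empirical curve over score
thresholds; AUC is trapezoidal, which with midpoint tie handling equals the
Mann–Whitney statistic. The combined model is least squares of the 0/1
response on PRS + PD-L1 fitted in training (logistic available behind a
flag); its linear predictor is scored on the test set.

## Synthetic-data generator

Defaults emulate a realistic gastric-tumor cohort regime: 375 tumors with
40 matched normals,
germline fraction 0.605, editing fraction 0.665 of somatic, germline MAF
uniform on (0.013, 0.5), somatic carrier fraction uniform on (0.02, 0.15),
germline VAF Beta(20,20)/Beta(40,2) for het/hom, somatic VAF Beta(2,6),
sequencing depth Poisson(60), genotyper coverage 95%, blood dropout 5%,
filter-tag rate 1%. Expression is negative-binomial (dispersion 0.03,
baseline mean 500 counts, per-sample library factors lognormal σ = 0.2)
around a latent log-scale Gaussian; planted cis effects add β × dosage to
the latent before the count draw, so downstream INT-scale estimates recover
β up to a small attenuation from count noise (the recovery test bounds the
regression slope in [0.9, 1.1]). Immune features are Gaussian latents with
additive planted effects. MPRA counts are negative-binomial (dispersion
0.15) around barcode-specific lognormal weights, with alternative-allele
means multiplied by 2^log2fc; setting dispersion and barcode spread to zero
gives a deterministic noiseless limit used for exact arithmetic tests.

What the generator does **not** emulate: alignment artifacts, strand
bias, purity/copy-number structure in VAFs, batch effects beyond one
optional latent factor, linkage between variants, realistic transcript
isoform complexity (one transcript per gene, single-interval regions), and
editing biochemistry (editing sites are positions, not A>G events). Tests
passing on this generator show the statistical machinery is calibrated and
the plumbing is correct — not that the classifier or QTL engine would
achieve the same operating characteristics on real tumor data.

## Problem sizes and numerics

The end-to-end demo default (375 samples, 500 genes, 2000 variants, 40
MPRA variants, 135 ICI patients) runs in well under a minute; the test and
acceptance suites use these package-chosen sizes: 10,000 null tests and
1000 coverage simulations for engine calibration, 200 replicates of
500 genes × 20 cis variants for gene-level FDR, 200 × 700-variant null MPRA
pools, 100 planted-effect MPRA simulations, 200 seeds for the PRS-vs-PD-L1
comparison, and a scaled-down demo for the byte-identity check. All
stochastic entry points take explicit seeds; the pipeline derives per-stage
seeds from one global seed and records them in the run manifest, making
repeated runs byte-identical. Degenerate inputs follow a consistent rule:
impossible configurations raise (zero-total samples, empty sampling spaces,
constant phenotype vectors), while per-item degeneracies degrade softly
with flags or log entries (untestable variants, skipped features, empty
signatures).
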