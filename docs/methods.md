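# Methods

This note documents the models behind `molqtl`, the defaults that matter,
what the synthetic cohort does and does not emulate, and the numerical
choices made where the design was genuinely open.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The synthetic cohort

The generator exists so that every downstream stage can be tested against a
known answer.  It emulates, at desk scale, the statistical structure of a
genotyped cohort with matched expression and chromatin-accessibility
profiles.

**Genotypes.** Diploid dosages arise from two haplotypes per individual.
Within an LD block all variants share an allele frequency drawn uniformly
from `maf_range` (default (0.05, 0.5)); along a block each haplotype copies
its neighbor's allele with probability `ld_copy_prob` (default 0.9) and
draws fresh otherwise, so pairwise correlation decays geometrically with
variant distance while block boundaries are independent.  Columns whose
realized MAF falls below 0.05 are resampled, mirroring the usual MAF > 5%
inclusion filter.  This deliberately avoids coalescent machinery: it gives
realistic decaying r² at a fraction of the complexity, but it does not
produce recombination hotspots, allele-frequency spectra, or long-range LD.

**Phenotypes.** Each causal locus pairs one variant with one gene and one
peak under one of three linear structural architectures with Gaussian
noise (`noise_sd`, default 1.0 SD):

- *chromatin-to-gene*: peak = β·dosage + covariates + ε;
  gene = γ·peak + covariates + ε
- *gene-to-chromatin*: the mirror
- *independent*: dosage affects peak and gene through separate paths

Architecture labels partition the loci exactly per the configured
fractions (largest-remainder rounding when not integral).  Allelic effects
β are drawn N(0, `effect_size_sd` = 0.8) with magnitude floored at
`min_effect` = 0.5 SD — no effect-size distribution is available to
emulate, so the defaults are free parameters chosen to make every planted
locus detectable at the default n = 400; the floor also pins down the
conditions of the direction-recovery experiment.  Path coefficients γ are
uniform on ±(0.6, 1.2).  Covariates mimic an aging-study design: age from
two uniform bands (20–41, 66–100), sex Bernoulli(0.5), both linear in every
phenotype.  Phenotypes are Gaussian throughout; count overdispersion,
library-size variation, and single-cell sparsity are *not* modeled, because
the downstream stages consume normalized matrices — passing tests therefore
says nothing about normalization robustness on real count data.

**Features and annotations.** Gene TSSs sit within ±50 kb of their causal
variant; peaks (600 bp) cover their causal variant for
`frac_causal_in_peak` = 0.6 of loci and sit 1–20 kb away otherwise, which
manufactures the C1/C2/C3 caQTL category variety.  A chromatin-state
segmentation tiles each chromosome in 50 kb segments labeled uniformly
from the six supergroups (Promoter, Enhancer_active, Enhancer_weak,
Transcribed, Repressed_polycomb, ZNF_Het_Quies) — uniform, so state labels
carry no signal and any detected enrichment on synthetic data is a false
positive by construction.  A simplified gene model (promoter ±2 kb of TSS,
alternating exon/intron blocks, flanking UTRs) supplies per-variant
genomic-region labels; the vote/priority logic downstream is what is under
test, not transcript-aware annotation.

**Sequence-model scores.** Only in-peak variants are scored.  The emitted
allelic log fold-change is c·standardize(true in-peak effect) +
√(1−c²)·noise with c = `chrombpnet_concordance` (default 0.7), scaled to a
log-aFC-like magnitude of 0.5.  Empirical p-values come from the null score
scale, and `significant` is exactly p < 0.05.  A fraction
(`frac_score_specific` = 0.1) of low-MAF (< 0.1) non-causal in-peak
variants receive boosted significant scores, emulating sequence-model-only
discoveries with no association support.

**GWAS credible sets.** Half (`gwas_sharing_frac` = 0.5) of the GWAS
credible sets are planted on a molQTL causal variant; per-variant z-scores
follow the LD profile of the causal variant (z_j = r_j·z_c + noise, z_c
uniform 7–10 in magnitude) and become Wakefield log Bayes factors at a
GWAS-scale sampling variance (n = 50,000).

Full regeneration under a fixed seed is byte-identical; this is asserted by
a manifest of file hashes on every pipeline run.

## Fine-mapping and its prior

The scan is a covariate-adjusted per-variant OLS (Frisch–Waugh projection
of covariates out of both phenotype and dosage; complete-case exclusion per
test for missing dosages).  The fine-mapper is single-effect by design:
multiple signals per region are out of scope and are simulated as separate
regions.  The Wakefield prior effect variance W defaults to 0.04 (prior SD
0.2), a conventional choice; it only fabricates realistically scaled lbfs
and PIPs, and no result depends on its exact value.  Credible sets take the
smallest PIP-descending prefix reaching coverage 0.95, with stable
tie-breaking in input order.  An all-zero z region degenerates to uniform
PIPs over the whole region.

Fine-mapping regions are ±1 Mb (expression) or ±250 kb (accessibility)
windows around lead variants, merged iteratively until no two regions share
a variant; regions overlapping the configured exclusion interval are
dropped.  Two exclusion defaults exist — chr6:25–36 Mb for molQTL region
building and chr6:25–34 Mb for the GWAS-enrichment background — because
both conventions are in circulation; they are kept as separate defaults
rather than reconciled.  The minimum region size defaults to 10 variants at
synthetic scale (the conventional value, 100, is one config field away).

## Colocalization

All hypothesis sums run in log space with log-sum-exp; the H3 mass
S1·S2 − S12 is computed as s1+s2+log1p(−exp(s12−s1−s2)) and set to −∞ for
single-variant inputs or when cancellation would go negative.  Priors
default to p1 = p2 = 1e-4, p12 = 1e-5; p12 > min(p1, p2) warns.  The
minimum shared-variant count defaults to 5 at synthetic scale (200 is the
conventional production value).  The post-colocalization variant filter
requires nominal p < 1e-3 in both traits and PIP > 0.01 in at least one of
the two credible sets by default; `pip_rule="both"` tightens that to both
sets, since the convention is genuinely ambiguous.

## Mediation posteriors and the global FDR

Each direction of each triplet yields two LRT statistics, n·log(RSS₀/RSS₁):
secondary linkage (B ~ E vs B ~ 1) and conditional independence
(B ~ A + E vs B ~ A), both ~χ²₁ under their nulls (checked by simulation).
RSS ratios beyond 1e12 are treated as exact collinearity and capped at 1e4.
Phenotypes are covariate-residualized and rank inverse-normal transformed
first; the INT offset is c = 0.5 (ranks map to (r−0.5)/n), with the Blom
offset 0.375 available.

Statistics become posteriors through a two-groups model fit across all
tests of a direction: p-values from the χ²₁ null, π₀ from Storey's
estimator, and a beta-uniform mixture f(p) = π₀ + (1−π₀)·α·p^(α−1) with α
fit by bounded MLE; the local fdr π₀/f(p) is the posterior of the null
(used directly for the conditional-independence test) and its complement
the posterior of the alternative (linkage test).  Two numerical choices
matter here:

- π₀ is the **maximum** of the Storey estimate over a λ grid that includes
  the usual 0.5.  A single-λ estimate is noisy downward on null-dominated
  pools (standard error ≈ 0.1 at 100 tests), and because the global FDR is
  1 − mean(posterior), underestimating π₀ caps the null-side posterior and
  can empty the retained set entirely.  Taking the grid maximum biases π₀
  upward, which is conservative for the FDR.
- π₀ is kept strictly below 1 (at 1 − 1e-3) so a residual alternative
  component always exists; without it, a pool that happens to estimate
  π₀ = 1 would assign null posterior 1 to even an extreme statistic.

The composite P(A→B) is the product of the two posteriors, motivated by the
product form of the composite test; a mean-combination is exposed as
config.  The primary linkage (E→A) is assumed satisfied — exposures are QTL
lead variants — but is still computed and logged as a diagnostic.  The
calling threshold steps down over the sorted posteriors and returns the
smallest threshold whose retained set keeps 1 − mean(posterior) ≤ the
target; ties at the threshold are retained together or the cut backs off
to the previous distinct value.  FDR is computed per direction; whether a
joint-direction FDR would be preferable is an open question and the
per-direction choice is flagged here.

The mixture fit requires ≥ 50 statistics; the pipeline skips the mediation
stage (with a logged warning) when fewer colocalized triplets exist, and
the default synthetic scale is set so the default run clears the minimum.

## Intersection, enrichment and permutation nulls

Membership groups use *incidence* units: one row per credible set (or per
colocalized CS pair, which is a single signal) and one row per orphan
score-significant variant; a CS counts as score-containing iff ≥ 1 member
variant is score-significant.  The seven groups are asserted mutually
exclusive and exhaustive on every run.  Effect concordance restricts to
in-peak (C1/C2) variants — sequence models only see local effects — and
reports Pearson r and r² per joint-significance class after allele
harmonization (swapped ref/alt flips the association beta; irreconcilable
pairs are dropped).

Fisher tests report the cross-product odds ratio with Woolf CIs
(Haldane +0.5 when any cell is zero; the exact hypergeometric p is always
computed on the uncorrected table).  Whether published Fisher CIs are Woolf
or exact-conditional is typically unstated; Woolf was chosen and only the
OR point estimate is checked against published values.  The GLM enrichment
uses a binomial GLM with logit link and locus-clustered sandwich errors
(Welch-style robustness to non-independent triplets within a locus);
|coefficient| > 15 is flagged as separation and the CI suppressed.  The
coverage comparison uses Welch's t by default (pooled-variance optional),
the safer reading of an unqualified "t-test".

The permutation null for score-hit enrichment draws, per credible set,
h* ~ Binomial(m, rate(chrom)) with chromosome-specific background rates
estimated from non-colocalized credible sets (pooled fallback for empty
chromosomes); the statistic is the class mean hit fraction and
p = (1 + #{stat* ≥ observed})/(n_perm + 1), so the floor is 1/(n_perm+1)
and a zero-exceedance result is reported as an upper bound (e.g.
"< 1e-05" at 10⁵ permutations).  Draws are vectorized and chunked to bound
memory.  MAF bin edges (0.05, 0.1, 0.2, 0.3, 0.4, 0.5) fix only the lowest
bin by convention; the rest are 0.1 steps.  TF-family enrichment consumes a
precomputed (variant, family, annotation) hit table — motif calling is out
of scope — and excludes families with fewer than 10 hits.

## Problem sizes and degenerate inputs

The default pipeline cohort is 400 individuals, 2 chromosomes × 40 LD
blocks × 20 variants (3,200 variants), 100 genes, 180 peaks, 80 causal
loci; a full run takes a few seconds on one CPU, and the direction-recovery
experiments use 100 loci per architecture at n = 400.  These sizes were
chosen so each experiment estimates its rates with usefully small binomial
error while remaining desk-scale.

Degenerate inputs are contracts, not surprises: cohorts below 30
individuals are refused; zero-variance dosages, constant phenotypes and
rank-deficient covariates raise (constant covariate columns are absorbed by
the intercept); empty credible sets are invalid at construction; zero-length
CS intervals (single-variant sets) have Jaccard 0 with everything except an
identical position, so they form singleton loci — a literal reading of the
min/max-position interval definition.

## Known limitations

- Single-effect fine-mapping only; no multi-signal bookkeeping, so the
  per-CS lbf vector *is* the signal's Bayes-factor profile.
- The mediation posterior estimator is a generic two-groups local-fdr
  model, not a reimplementation of any specific package's internal null;
  validation is by parameter recovery on planted architectures, not
  numeric equality with external tools.
- Synthetic LD is blockwise-stationary; conclusions about fine-mapping
  resolution under realistic LD do not transfer.
- Feedback loops are reported (triplets significant in both directions)
  but not modeled.
- Chromatin-state and region labels on synthetic data are uninformative by
  construction; annotation tests verify bookkeeping, not biology.
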