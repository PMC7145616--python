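# Methods

This note records the statistical model behind each stage, the defaults and
why they are what they are, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Quality control

Variant-level filters run in a fixed order — missing rsID, MAF ≤ 0.05,
non-autosomes, MHC — and each reports its removal count; because the
filters are independent predicates, the surviving set equals the
intersection of the per-filter keeps, which the tests assert.

* **Genomic inflation factor.** λ = median(χ²₁ quantile of 1 − p) / 0.4549364,
  the standard median-based genomic-control estimator (the defining
  reference names λ but no formula). The estimator's sampling sd is roughly
  1/(2·f(m)·√n·m) with m the null median; at 20,000 independent variants it
  is ≈ 0.017, which sets the problem sizes used in the calibration tests.
* **Gates.** Strictly more than 100,000 analysed variants; λ ≤ 1.5 (strict
  on exceedance, with a 10⁻⁹ relative epsilon so float noise at the
  boundary cannot flip the decision); a metadata ancestry flag (European by
  default) — ancestry is curation information, never inferred from data.
* **Order question.** Whether λ is computed before or after the MAF filter
  is genuinely open; the default computes it on the post-missing-rsID,
  pre-MAF set (`QCConfig.lambda_on` switches this). The variant-count gate
  uses the same set.
* The MHC default is chr6:25–35 Mb (GRCh37), configurable; no coordinates
  are fixed by the method itself.

## LD-aware gene scores

The gene statistic is the sum of 1-df chi-square quantiles of the SNP
P-values (two-sided P; effect signs are discarded, as in standard gene-based
tests). Under the null, T ~ Σⱼ λⱼZⱼ² with λⱼ the eigenvalues of the SNP
correlation matrix estimated from reference dosages.

Numerical evaluation of the upper tail, in order:

1. **Equal eigenvalues** (single SNP, independent SNPs, perfect LD):
   scaled chi-square closed form, exact.
2. **Chernoff bound screen.** The saddlepoint exponential bound is computed
   first; when it is below 10⁻¹², the bound itself is returned — quadrature
   noise (absolute ~10⁻⁹) would otherwise swamp so small a tail. The bound
   also caps the final result, so the tail is monotone decreasing far out.
3. **Imhof inversion.** The Gil-Pelaez/Imhof integral evaluated with
   adaptive infinite-range quadrature (QAGI with extrapolation handles the
   oscillatory integrand); the integrand is compiled with numba for speed,
   with a pure-Python fallback. Typical absolute accuracy ~10⁻⁵–10⁻⁶.
4. **Monte-Carlo fallback** (10⁶ draws, seeded) whenever the quadrature's
   own error estimate exceeds 10⁻⁴ or its value leaves [0, 1].

Eigenvalues below 10⁻⁸ of the largest are dropped before inversion
(stability); negative eigenvalues of near-singular empirical LD are clipped
to zero, the matrix being projected to the nearest PSD by truncation. Genes
whose window exceeds 5000 SNPs are scored on the top-variance subset — a
guard against pathological inputs, logged when it triggers. Genes whose
SNPs all lack reference coverage (or all have zero dosage variance) are
"poorly genotyped": status `failed`. The SNP→gene window is the gene body
± 50 kb with inclusive boundaries; a SNP may serve several genes.

Only the SUM-type statistic is implemented; a MAX-type statistic (minimum
SNP P with multiplicity correction) is out of scope.

## Tissue specificity

Expression is log₂(x+1)-transformed before scoring — raw expression's heavy
tails would otherwise dominate the linear-model statistics. The t-score is
the indicator coefficient's t-statistic in a one-vs-rest regression with
covariates as fixed effects; with two tissues and no covariates it reduces
exactly to the pooled two-sample t (asserted to 10⁻¹⁰). Genes fitted
exactly (e.g. flat expression) score 0 by definition rather than 0/0. The
z-score standardises per-gene tissue means across tissues with the
population sd; a single-tissue panel has no z-score and is a configuration
error. `auto` selects t-scores when every tissue has ≥ 30 samples
(mirroring the GTEx/ENCODE panel split) and z-scores otherwise.

Top-fraction sets take the floor(fraction·G) highest-scoring genes per
tissue (default 5%); cutoff ties break lexicographically by gene ID so the
sets are deterministic, and the sets are invariant under any monotone
transform of a tissue's scores.

## Enrichment

The universe for the 2 × 2 table is the intersection of successfully scored
genes and panel genes — the only choice under which all four margins are
well defined. The statistic is the Pearson chi-square without continuity
correction; the one-sided P is half the upper χ²₁ tail when the observed
overlap exceeds its expectation, 1 minus that half below it, and exactly
0.5 at equality. A degenerate margin gives X² = 0, hence P = 0.5.

*Known limitation:* the halved-tail normal approximation is
anti-conservative when the expected overlap is small (single digits); with
TAG sets of 20–3000 genes against 5% tissue sets in a ~18,000-gene
universe the expected counts are large enough that the type-I error is
calibrated (checked at 0.05 ± 0.02), and a fixed grid of large-margin
tables agrees with the one-sided Fisher exact P within 0.02.

TAG sets use strict inequality (P < threshold), are nested by construction,
and qualify at 20–3000 genes; a study with no qualified set is excluded.

### GSEA validation

For each of the top 3 tissues (ranked by minimum P over qualified
thresholds; ties broken by larger overlap at the best cell, then name), the
TAG set with the smallest enrichment P is tested against genes ranked by
decreasing specificity score. The enrichment score is the classic weighted
running sum (weight exponent 1 on |score|, misses stepping −1/(N−m));
the extremum of largest magnitude is the ES, computed only at candidate
positions (immediately after a hit for maxima, immediately before for
minima), which makes a permutation cost O(m log m).

The permutation null re-draws the m gene labels uniformly without
replacement — on summary-level inputs a phenotype permutation is not
available, so gene-label resampling is the only null realisable here.
NES = ES / |mean of same-sign permutation ES| (classic convention; the sign
of NES always matches ES); the permutation P uses the add-one estimator
(1 + #{same-sign |ES′| ≥ |ES|})/(n_perm + 1), so it is never 0. All
permutation runs are seeded and the seed is recorded in report provenance.

## Duplicate detection and comparison

Study pairs are correlated on raw gene P-values over their common
successfully-scored genes (≥ 100 required, else the pair is skipped with a
warning); −log₁₀ P correlation is available behind a flag. PCC > 0.99
flags a duplicate; merely similar studies (≈ 0.98) stay distinct. Within a
connected group of duplicates the retained study is the first by study ID —
a deterministic replacement for random choice, with a seeded random mode
for fidelity. Tissue-overlap statistics take the study universe size as a
required argument (the method fixes no default universe) and recompute
percentages from counts at render time, so stored numbers cannot drift.

## Synthetic data

The generator plants known ground truth at the statistical level the
pipeline actually consumes:

* **Expression panel:** baseline log₂ expression i.i.d. N(5, 1); planted
  genes (n_causal_genes per tissue, disjoint) gain `specificity_effect`
  (default 4 log₂-units) in their tissue; values are exported on the raw
  scale so the pipeline's log transform recovers the simulated values
  exactly. Defaults: 30 samples/tissue, 5 tissues, 400 genes with 20
  planted per tissue — sized so the loosest TAG set clears the 20-gene
  qualification floor and planted genes exactly fill a top-5% set.
* **Genotypes:** per-gene LD blocks; two latent Gaussian haplotypes with
  equicorrelation `ld_block_rho` (default 0.5) thresholded at MAFs drawn
  uniform(0.06, 0.5) — above the MAF ≤ 0.05 filter, so simulated variants
  survive QC by design. Blocks are independent (cross-block LD ≈ 0).
* **Summary statistics:** per-block z-scores from MVN(R·δ, R) with R the
  empirical block LD — the standard summary-level simulation, chosen over
  individual-level phenotypes for speed; δ is 0 in non-causal blocks and
  N(noncentrality, effect_sd²) per SNP (defaults 5 and 1) in the causal
  tissue's blocks. Effects and SEs follow the z/√n convention.

All streams spawn deterministically from one seed; identical configurations
are byte-identical. What the generator does **not** emulate: realistic human
LD maps and allele-frequency spectra, polygenic background, population
stratification, expression batch structure or covariate confounding (a
covariate hook exists but the generator plants none). Passing tests
therefore demonstrate the pipeline's internal correctness and calibration
under its own model assumptions, not robustness to those real-data
complications.

### Problem sizes used in the test and acceptance runs

Chosen so the whole suite runs comfortably on one CPU while keeping each
statistical check at ~2–3σ discrimination: 300-gene genomes with 4 SNPs per
gene and 15 causal genes for end-to-end recovery (100 seeds in the tests,
60 in the acceptance script); 4000 genes × 5 independent SNPs for the null-λ
study (estimator sd ≈ 0.017 against a ±0.05 band); 18,000-gene universes
with 1000-gene TAGs for enrichment calibration; 10⁶ draws for the
Monte-Carlo tail oracle; 2000 genes for the null uniformity (KS) check of
gene P-values.

## Interfaces and formats

Internal genomic coordinates are 1-based inclusive everywhere; only the BED
reader converts (interval [a, b) → (a+1, b)). Chromosome labels are
normalised by stripping a leading `chr` and uppercasing (M → MT). Summary
statistics are mapped to the internal schema through an explicit
column map (config file), with a header-sniffing convenience for common
dialects — explicit mapping wins over magic for reproducibility. Allele
frequencies above 0.5 are folded to MAF. Duplicated positions with distinct
rsIDs are kept; repeated rsIDs beyond the first are dropped with a count.
GFF parsing goes through gffutils, VCF genotypes through cyvcf2 (ALT dosage,
mean-imputed missing calls), tables through pandas. Reports are JSON with a
schema version, accompanied by TSVs; a consistency validator re-derives
every derived number in a report from its parts.
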