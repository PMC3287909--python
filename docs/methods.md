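# Methods

## The statistic

For each gene the test collapses minor alleles at rare variants
(MAF < 0.01 by default, strict inequality) into a per-individual mutation
count: the sum of minor-allele dosages over the gene's rare sites, so a
heterozygote contributes 1 and a rare homozygote 2 (an alternative
`count_mode=carrier` counts carried sites instead). Writing `P_i` and `Q_j`
for case and control counts, the statistic is

    T_G = (P̄ − Q̄)² / ( S² · (1/n_P + 1/n_Q) ),
    S²  = [ Σ (Pᵢ − P̄)² + Σ (Qⱼ − Q̄)² ] / (N − 2),

compared against χ²(1). T_G is identically the square of the equal-variance
two-sample t statistic; the test suite verifies this equivalence against
scipy's independent implementation to 1e-10 relative error. The pooled form
(denominator N − 2) is the default; a `variance=total` switch instead uses
the sample variance of all counts around the grand mean (denominator
N − 1), which differs only under association and is provided for
sensitivity analysis. The grand mean R̄ is computed and stored but plays no
role in the default statistic.

**Asymptotics and sparsity.** χ²(1) is an asymptotic reference; burden
counts are discrete and often extremely sparse (a gene may have a handful
of carriers). In that regime the test is conservative — the attainable
p-values are coarse and the rejection rate at small α falls below nominal.
The calibration suite therefore checks the well-populated regime (Poisson
counts with mean 1, 500 per group), where the empirical levels at 0.01 and
0.001 match nominal within Monte Carlo error and the mean of T_G is ≈ 1.
On sparse data users should expect conservative behaviour, not inflation.

## Conventions and edge cases

- **MAF** is the folded frequency min(f, 1 − f) of the alternate allele
  among typed genotypes; at f = 0.5 the alternate allele is treated as
  minor. MAFs are estimated from the full analyzed sample unless per-variant
  population frequencies are supplied (`--maf-file` / `external_mafs`).
- **Rare** means MAF strictly below the threshold (default 0.01); the
  threshold is a parameter. No multiple-testing correction is applied —
  significance levels are fixed per-gene thresholds.
- **Gene assignment** is by position, inclusive on both ends of the 1-based
  interval; a variant inside overlapping genes counts toward every gene
  containing it. BED input (0-based half-open) is converted on read.
- **Missing genotypes** count 0 toward the burden and are excluded from the
  MAF denominator. This is the simplest well-defined rule; datasets with
  substantial missingness deserve imputation upstream.
- **Degenerate genes** (S² = 0) are never dropped: they are flagged, with
  p = 1 when the group means also agree (T_G would be 0/0 but no evidence
  either way) and an undefined p otherwise. Keeping them preserves the
  fixed gene-count denominators used by the evaluation layer.
- At least 2 cases and 2 controls are required (the pooled variance needs
  N − 2 ≥ 2 to be a stable scale estimate with both groups contributing).

## The synthetic study generator

`geneburden.simulate` emulates a GAW17-style replicate design: one fixed
genotype draw, many phenotype replicates.

- **Gene structure.** SNP counts per gene follow a discretized log-normal,
  `count = max(1, round(LogNormal(μ, σ)))` with μ = 1.38287, σ = 1.20990,
  solved so the distribution's mean is 8.33 and variance 227.6 — the
  heavy-tailed SNPs-per-gene profile of a mini-exome. Genes are laid
  end-to-end on synthetic chromosomes with SNP positions uniform inside
  each gene.
- **MAF spectrum.** True MAFs follow the power law `0.5·u¹²` (u uniform),
  putting roughly 70% of variants below 0.01 and many below the resolution
  of a ~700-sample study — mimicking the singleton-heavy spectrum of
  sequence data. Genotypes are Binomial(2, MAF) per individual: no linkage
  disequilibrium, population structure, or relatedness.
- **Causal architecture.** A configurable number of causal genes (default
  36 of 3,205) is split round-robin among the traits Q1, Q2, Q4 and a
  latent liability. Within a causal gene a fraction of SNPs (default 0.3)
  carries a constant non-negative per-allele effect; only SNPs with true
  MAF below `causal_maf_max` (default 0.01) are eligible, since the design
  models rare susceptibility mutations and effects on common variants
  would place the signal outside the rare-burden count by construction.
- **Phenotype.** Each trait is its genetic score plus standard-normal
  noise; total liability is the weighted trait sum (default equal weights)
  plus independent noise. Affection is assigned by the empirical liability
  quantile, so exactly `round(prevalence · n)` individuals are affected
  (default prevalence 0.3, n = 700 — stand-ins for a GAW17-sized study; an
  absolute-threshold mode is available). Noise is redrawn per replicate;
  genotypes and effects are fixed.
- **Seeding.** Two independent streams derived from the master seed — one
  for structure/genotypes/effects, one keyed by replicate index for
  phenotype noise — so a genotype set is reusable across replicate sets
  and every replicate is reproducible from (seed, index).

What passing tests on this generator do **not** show: behaviour under
linkage disequilibrium, confounding by ancestry, genotype missingness or
calling error, or the specific allelic architecture of any real dataset.

## Evaluation

Per replicate and significance level α: type I error is the count of
significant known-null genes over the total null-gene count, power the same
ratio over causal genes. Significance is strict (p < α); degenerate genes
stay in denominators but cannot be significant. Per-gene tallies count the
replicates in which a gene is significant; that frequency is the per-gene
power estimate. Aggregation reports the mean and sample SD (ddof = 1)
across replicates, with SD flagged undefined for a single replicate.
Percentages in tables are displayed to one decimal; full precision is kept
internally.

## Problem sizes used in the checks

The null-calibration check (also `scripts/acceptance.py`) uses 100,000
genes with iid Poisson(1) counts, 500 per group — large enough that the
3-binomial-SE band at α = 0.001 is ±0.0003. The end-to-end power check uses
80 genes, 700 individuals, 20 phenotype replicates and three effect levels
(1, 3, 6 per allele on the liability scale) with one heavily loaded causal
gene; these sizes give stable ordering of power across effect levels while
keeping the suite fast.

## Known limitations

- The χ²(1) reference is asymptotic; no permutation or exact option.
- No covariates, variant weights, dispersion/variance-component tests, or
  family designs; variants are assumed independent in the simulator.
- Multi-allelic VCF records are skipped by default (or naively decomposed
  per alternate allele with `multiallelic=split`); no BGEN/PLINK input.
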