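"""Synthetic GAW17-style replicate datasets.

Emulates the design of the Genetic Analysis Workshop 17 mini-exome
simulation: a single fixed set of rare-variant genotypes, shared across
many phenotype replicates, with disease status produced by a liability
threshold model.  Three quantitative traits (Q1, Q2, Q4) and a latent
liability component each receive genetic contributions from a subset of
causal genes; the total liability is a weighted sum of the four plus
independent noise, and the individuals in the upper tail of the realized
liability distribution are affected.

Defaults mirror the published summaries of that design: 3,205 genes of
which 36 are causal, a heavy-tailed SNPs-per-gene distribution with mean
8.33 and variance 227.6, a minor-allele-frequency spectrum concentrated
below 0.01, and 200 phenotype replicates over one genotype draw.  Variants
are sampled independently under Hardy-Weinberg equilibrium: there is no
linkage disequilibrium, population structure, or relatedness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .core import GeneRegion, GenotypeMatrix, PhenotypeVector, VariantRecord

__all__ = ["SimConfig", "SimReplicate", "draw_gene_structure", "draw_genotypes",
           "simulate_phenotype", "simulate_study"]

# Discretized log-normal for SNPs per gene: count = max(1, round(X)),
# X ~ LogNormal(mu, sigma).  Parameters solve for mean 8.33, variance 227.6.
SNPS_PER_GENE_MU = 1.3828746577124944
SNPS_PER_GENE_SIGMA = 1.2098973572124632

GENE_SPACING = 10_000  # bp between consecutive genes on a synthetic chromosome
BP_PER_SNP = 500  # gene length scales with its SNP count
GENES_PER_CHROM = 150


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study design.

    The SNPs-per-gene distribution is a discretized log-normal clamped to a
    minimum of one SNP; its default parameters reproduce a mean of 8.33
    SNPs per gene with variance 227.6.  The MAF spectrum is a power law
    ``0.5 * u**maf_exponent`` with ``u ~ Uniform(0, 1)``, which for the
    default exponent places roughly three-quarters of variants below the
    0.01 rare-variant threshold.  Causal genes are split round-robin among
    Q1, Q2, Q4 and the latent liability; within a causal gene a fraction of
    SNPs carry a per-minor-allele effect on that trait.
    """

    n_individuals: int = 700
    n_genes: int = 3205
    causal_gene_count: int = 36
    causal_snp_fraction: float = 0.3
    causal_maf_max: float = 0.01
    effect_size: float = 1.0
    snps_per_gene_mu: float = SNPS_PER_GENE_MU
    snps_per_gene_sigma: float = SNPS_PER_GENE_SIGMA
    maf_exponent: float = 12.0
    trait_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    liability_noise_sd: float = 1.0
    prevalence: float = 0.3
    n_replicates: int = 200
    causal_gene_selection: str = "random"  # or "most_snps"
    threshold_mode: str = "quantile"  # or "absolute"
    absolute_threshold: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.causal_gene_count > self.n_genes:
            raise ValueError("causal_gene_count exceeds n_genes")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if self.effect_size < 0:
            raise ValueError("effect sizes must be non-negative")
        if not (0.0 <= self.causal_snp_fraction <= 1.0):
            raise ValueError("causal_snp_fraction must be in [0, 1]")
        if self.causal_gene_selection not in ("random", "most_snps"):
            raise ValueError(f"unknown causal_gene_selection {self.causal_gene_selection!r}")


@dataclass
class GeneticArchitecture:
    """Causal gene/SNP assignment shared across replicates."""

    causal_genes: set[str]
    # variant column index -> (trait index in {0: Q1, 1: Q2, 2: Q4, 3: latent}, beta)
    snp_effects: dict[int, tuple[int, float]]
    gene_trait: dict[str, int]


@dataclass
class SimReplicate:
    """One synthetic dataset: fixed genotypes plus replicate-specific phenotype."""

    genotypes: GenotypeMatrix
    variants: list[VariantRecord]
    genes: list[GeneRegion]
    traits: np.ndarray  # (n_individuals, 4): Q1, Q2, Q4, latent
    liability: np.ndarray
    phenotype: PhenotypeVector
    causal_genes: set[str]
    replicate_index: int


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, *stream)))


def draw_gene_structure(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[GeneRegion], list[VariantRecord]]:
    """Lay out genes end-to-end on synthetic chromosomes and place SNPs.

    SNP counts per gene come from the configured discretized log-normal;
    each variant gets a true MAF from the power-law spectrum and a position
    strictly inside its gene's bounds.
    """
    if rng is None:
        rng = _rng(config.seed, 0)
    mean_check = float(
        np.exp(config.snps_per_gene_mu + config.snps_per_gene_sigma**2 / 2)
    )
    if mean_check < 1.0:
        raise ValueError("SNPs-per-gene distribution implies mean < 1")

    counts = np.maximum(
        1,
        np.round(
            rng.lognormal(config.snps_per_gene_mu, config.snps_per_gene_sigma, config.n_genes)
        ),
    ).astype(int)

    genes: list[GeneRegion] = []
    variants: list[VariantRecord] = []
    for i, k in enumerate(counts):
        chrom = f"chr{i // GENES_PER_CHROM + 1}"
        offset = (i % GENES_PER_CHROM) * GENE_SPACING * 10
        start = offset + 1
        end = start + max(int(k) * BP_PER_SNP, 1000) - 1
        name = f"GENE{i + 1:04d}"
        genes.append(GeneRegion(name, chrom, start, end))
        pos = np.sort(rng.choice(np.arange(start, end + 1), size=k, replace=False))
        mafs = 0.5 * rng.random(k) ** config.maf_exponent
        for j, (p, m) in enumerate(zip(pos, mafs)):
            variants.append(
                VariantRecord(f"{name}_snp{j + 1}", chrom, int(p), "A", "T", float(m))
            )
    return genes, variants


def draw_genotypes(
    variants: list[VariantRecord], n_individuals: int, rng: np.random.Generator
) -> np.ndarray:
    """Hardy-Weinberg dosages: Binomial(2, maf) per individual per variant."""
    mafs = np.array([v.maf for v in variants], dtype=float)
    if np.any((mafs < 0) | (mafs > 0.5)):
        raise ValueError("variant MAFs must lie in [0, 0.5]")
    return rng.binomial(2, mafs, size=(n_individuals, mafs.size)).astype(float)


def _assign_architecture(
    config: SimConfig,
    genes: list[GeneRegion],
    variants: list[VariantRecord],
    rng: np.random.Generator,
) -> GeneticArchitecture:
    """Pick causal genes, split them among the four traits, assign SNP effects."""
    gene_cols: dict[str, list[int]] = {g.gene: [] for g in genes}
    for col, v in enumerate(variants):
        gene_cols[v.variant_id.rsplit("_snp", 1)[0]].append(col)

    if config.causal_gene_selection == "most_snps":
        order = sorted(genes, key=lambda g: len(gene_cols[g.gene]), reverse=True)
        causal = [g.gene for g in order[: config.causal_gene_count]]
    else:
        causal = list(
            rng.choice([g.gene for g in genes], size=config.causal_gene_count, replace=False)
        )

    gene_trait = {g: i % 4 for i, g in enumerate(causal)}
    snp_effects: dict[int, tuple[int, float]] = {}
    for g in causal:
        cols = gene_cols[g]
        # Susceptibility mutations are rare: only SNPs under causal_maf_max
        # are eligible to carry effects.
        eligible = [c for c in cols if variants[c].maf < config.causal_maf_max]
        n_causal = min(
            len(eligible), max(1, int(round(config.causal_snp_fraction * len(cols))))
        )
        if n_causal == 0:
            continue
        chosen = rng.choice(eligible, size=n_causal, replace=False)
        for c in chosen:
            snp_effects[int(c)] = (gene_trait[g], config.effect_size)
    return GeneticArchitecture(set(causal), snp_effects, gene_trait)


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    variants: list[VariantRecord],
    genes: list[GeneRegion],
    architecture: GeneticArchitecture,
    config: SimConfig,
    replicate_index: int,
    rng: np.random.Generator | None = None,
) -> SimReplicate:
    """Draw one phenotype replicate over fixed genotypes.

    Each trait is its genetic score plus standard-normal noise; total
    liability is the weighted trait sum plus independent noise.  Under the
    default quantile threshold rule exactly ``round(prevalence * n)``
    individuals — those with the highest realized liability — are affected.
    """
    if rng is None:
        rng = _rng(config.seed, 1, replicate_index)
    n = genotypes.n_samples

    genetic = np.zeros((n, 4))
    for col, (trait, beta) in architecture.snp_effects.items():
        genetic[:, trait] += beta * genotypes.dosage[:, col]
    traits = genetic + rng.standard_normal((n, 4))

    w = np.asarray(config.trait_weights, dtype=float)
    liability = traits @ w + config.liability_noise_sd * rng.standard_normal(n)

    if config.threshold_mode == "quantile":
        n_affected = int(round(config.prevalence * n))
        order = np.argsort(-liability, kind="stable")
        affected = np.zeros(n, dtype=bool)
        affected[order[:n_affected]] = True
    elif config.threshold_mode == "absolute":
        affected = liability > config.absolute_threshold
    else:
        raise ValueError(f"unknown threshold_mode {config.threshold_mode!r}")

    if affected.sum() < 2 or (~affected).sum() < 2:
        raise ValueError(
            "fewer than 2 cases or 2 controls; increase n_individuals or adjust prevalence"
        )

    phenotype = PhenotypeVector(list(genotypes.sample_ids), affected)
    return SimReplicate(
        genotypes=genotypes,
        variants=variants,
        genes=genes,
        traits=traits,
        liability=liability,
        phenotype=phenotype,
        causal_genes=set(architecture.causal_genes),
        replicate_index=replicate_index,
    )


def build_study(config: SimConfig):
    """Fixed part of a study: gene structure, genotypes, causal architecture.

    Uses two independent seed streams derived from ``config.seed`` — one
    for structure/genotypes, one per phenotype replicate — so a genotype
    set can be reused across replicate sets.
    """
    structure_rng = _rng(config.seed, 0)
    genes, variants = draw_gene_structure(config, structure_rng)
    dosage = draw_genotypes(variants, config.n_individuals, structure_rng)
    genotypes = GenotypeMatrix(
        sample_ids=[f"ind{i + 1:04d}" for i in range(config.n_individuals)],
        variant_ids=[v.variant_id for v in variants],
        dosage=dosage,
    )
    architecture = _assign_architecture(config, genes, variants, _rng(config.seed, 2))
    return genes, variants, genotypes, architecture


def simulate_study(config: SimConfig) -> Iterator[SimReplicate]:
    """Yield ``config.n_replicates`` replicates sharing one genotype draw."""
    genes, variants, genotypes, architecture = build_study(config)
    for r in range(config.n_replicates):
        yield simulate_phenotype(genotypes, variants, genes, architecture, config, r)
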