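"""Gene-based rare-allele burden test.

The statistic implemented here collapses the rare minor alleles inside a
gene into a single per-individual count ("mutation count"): for each
individual we sum the minor-allele dosage over every variant in the gene
whose minor allele frequency (MAF) is below a threshold (0.01 by default).
Writing ``P_i`` for the count of case individual ``i`` and ``Q_j`` for the
count of control individual ``j``, with group sizes ``n_P`` and ``n_Q`` and
``N = n_P + n_Q``, the pooled sample variance is

    S^2 = [ sum_i (P_i - Pbar)^2 + sum_j (Q_j - Qbar)^2 ] / (N - 2)

and the gene-level test statistic is the squared standardized difference of
mean burden,

    T_G = (Pbar - Qbar)^2 / ( S^2 * (1/n_P + 1/n_Q) ),

which under no association is asymptotically chi-square with one degree of
freedom.  ``T_G`` is exactly the square of the classical equal-variance
two-sample t statistic, which the test suite uses as an independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "GeneRegion",
    "PhenotypeVector",
    "GeneBurden",
    "GeneTestResult",
    "compute_maf",
    "select_rare",
    "assign_variants_to_genes",
    "burden_counts",
    "pooled_variance",
    "total_variance",
    "t_g_statistic",
    "t_g_from_counts",
    "scan_genes",
]

DEFAULT_MAF_THRESHOLD = 0.01


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant site.

    ``maf`` is the folded minor allele frequency in [0, 0.5]; it may be
    estimated from the analyzed sample or supplied externally (e.g., known
    population frequencies).
    """

    variant_id: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str = "N"
    alt_allele: str = "N"
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1, got {self.pos}")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"{self.variant_id}: maf must be in [0, 0.5], got {self.maf}")


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage table.

    ``dosage`` holds alternate-allele counts per genotype as floats, with
    ``nan`` marking missing calls.  Minor-allele orientation is resolved
    downstream by folding (columns whose alternate-allele frequency exceeds
    0.5 are flipped when burdens are formed).
    """

    sample_ids: list[str]
    variant_ids: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = self.dosage[~valid][0]
            raise ValueError(f"dosage entries must be 0, 1, 2 or missing; found {bad}")
        self._col_index = {v: i for i, v in enumerate(self.variant_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def columns(self, variant_ids: Sequence[str]) -> np.ndarray:
        """Column indices for the given variant ids."""
        try:
            return np.array([self._col_index[v] for v in variant_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]!r} not present in genotype matrix") from None


@dataclass(frozen=True)
class GeneRegion:
    """Named 1-based, inclusive genomic interval."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"{self.gene}: start must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class PhenotypeVector:
    """Case/control status per sample, order-aligned with a genotype matrix."""

    sample_ids: list[str]
    is_case: np.ndarray  # boolean

    def __post_init__(self) -> None:
        self.is_case = np.asarray(self.is_case, dtype=bool)
        if len(self.sample_ids) != self.is_case.size:
            raise ValueError("sample_ids and status lengths differ")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample IDs: {dupes}")

    @property
    def n_case(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_control(self) -> int:
        return int((~self.is_case).sum())


@dataclass
class GeneBurden:
    """Per-individual rare-allele counts for one gene, split by group.

    Carries the sufficient statistics of the test: group means ``case_mean``
    (Pbar) and ``control_mean`` (Qbar), the grand mean over the total sample
    (Rbar), and the pooled variance ``S^2``.
    """

    gene: str
    case_counts: np.ndarray
    control_counts: np.ndarray
    case_mean: float
    control_mean: float
    grand_mean: float
    pooled_variance: float
    n_case: int
    n_control: int
    n_total: int

    @property
    def n(self) -> int:
        return self.n_total

    @classmethod
    def from_counts(
        cls, gene: str, case_counts: Sequence[float], control_counts: Sequence[float]
    ) -> "GeneBurden":
        """Build a burden directly from per-individual counts."""
        p = np.asarray(case_counts, dtype=float)
        q = np.asarray(control_counts, dtype=float)
        n = p.size + q.size
        return cls(
            gene=gene,
            case_counts=p,
            control_counts=q,
            case_mean=float(p.mean()),
            control_mean=float(q.mean()),
            grand_mean=float(np.concatenate([p, q]).mean()),
            pooled_variance=pooled_variance(p, q) if n >= 3 else math.nan,
            n_case=p.size,
            n_control=q.size,
            n_total=n,
        )


@dataclass
class GeneTestResult:
    """Outcome of the burden test for one gene.

    ``t_g`` and ``p_value`` are ``nan`` when undefined.  A gene is
    degenerate when the pooled variance is zero (e.g., monomorphic for rare
    alleles); degenerate genes with equal group means get p = 1, degenerate
    genes with unequal means get an undefined p.
    """

    gene: str
    t_g: float
    p_value: float
    n_rare_snps: int
    degenerate: bool
    df: int = 1
    chrom: str = ""
    n_snps: int = 0
    n_case: int = 0
    n_control: int = 0
    case_mean: float = math.nan
    control_mean: float = math.nan
    pooled_var: float = math.nan

    def is_significant(self, alpha: float) -> bool:
        """Strictly below alpha; undefined p-values are never significant."""
        return not math.isnan(self.p_value) and self.p_value < alpha


def compute_maf(dosages: Iterable[float]) -> float:
    """Folded minor allele frequency from one variant's dosage column.

    Missing entries (``nan``) are excluded from the denominator.  Returns
    ``min(f, 1 - f)`` where ``f`` is the alternate-allele frequency among
    typed individuals.
    """
    d = np.asarray(list(dosages) if not isinstance(dosages, np.ndarray) else dosages, dtype=float)
    typed = ~np.isnan(d)
    n_typed = int(typed.sum())
    if n_typed == 0:
        raise ValueError("variant has no typed genotypes; MAF undefined")
    f = float(d[typed].sum()) / (2.0 * n_typed)
    return min(f, 1.0 - f)


def select_rare(
    variants: Sequence[VariantRecord], threshold: float = DEFAULT_MAF_THRESHOLD
) -> list[VariantRecord]:
    """Variants with MAF strictly below ``threshold``.

    The strict inequality matters: a variant with MAF exactly at the
    threshold is excluded.
    """
    if threshold < 0:
        raise ValueError(f"MAF threshold must be non-negative, got {threshold}")
    missing = [v.variant_id for v in variants if v.maf is None]
    if missing:
        raise ValueError(f"variants without computed MAF: {missing[:5]}")
    return [v for v in variants if v.maf < threshold]


def assign_variants_to_genes(
    variants: Sequence[VariantRecord], genes: Sequence[GeneRegion]
) -> dict[str, list[str]]:
    """Map each gene to the variants whose position falls inside its bounds.

    Bounds are inclusive on both ends (1-based).  A variant inside two
    overlapping genes is assigned to both; genes without variants map to an
    empty list.
    """
    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    for vs in by_chrom.values():
        vs.sort(key=lambda v: v.pos)

    out: dict[str, list[str]] = {}
    for g in genes:
        vs = by_chrom.get(g.chrom, [])
        if vs:
            pos = np.array([v.pos for v in vs])
            lo = int(np.searchsorted(pos, g.start, side="left"))
            hi = int(np.searchsorted(pos, g.end, side="right"))
            out[g.gene] = [vs[i].variant_id for i in range(lo, hi)]
        else:
            out[g.gene] = []
    return out


def _minor_dosage(cols: np.ndarray) -> np.ndarray:
    """Orient a block of dosage columns to count minor alleles.

    Columns whose alternate-allele frequency exceeds 0.5 are flipped
    (``2 - d``); at exactly 0.5 the alternate allele is kept as minor.
    """
    if cols.size == 0:
        return cols
    with np.errstate(invalid="ignore"):
        f = np.nanmean(cols, axis=0) / 2.0
    flip = f > 0.5
    if flip.any():
        cols = cols.copy()
        cols[:, flip] = 2.0 - cols[:, flip]
    return cols


def burden_counts(
    gene: GeneRegion,
    rare_variant_ids: Sequence[str],
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeVector,
    count_mode: str = "dosage",
    variance: str = "pooled",
) -> GeneBurden:
    """Per-individual rare-allele counts for one gene, with group summaries.

    ``count_mode='dosage'`` sums minor-allele dosage (a rare homozygote
    contributes 2); ``'carrier'`` counts sites carried (per-site indicator).
    Missing genotypes contribute 0 to the count.
    """
    if genotypes.sample_ids != phenotype.sample_ids:
        raise ValueError("genotype and phenotype sample IDs are not aligned")
    n_p = phenotype.n_case
    n_q = phenotype.n_control
    if n_p < 1 or n_q < 1:
        raise ValueError(f"{gene.gene}: need at least one case and one control")

    if len(rare_variant_ids) == 0:
        counts = np.zeros(genotypes.n_samples)
    else:
        cols = _minor_dosage(genotypes.dosage[:, genotypes.columns(rare_variant_ids)])
        if count_mode == "carrier":
            cols = (cols > 0).astype(float)
        elif count_mode != "dosage":
            raise ValueError(f"unknown count_mode {count_mode!r}")
        counts = np.nansum(cols, axis=1)

    p = counts[phenotype.is_case]
    q = counts[~phenotype.is_case]
    p_bar = float(p.mean())
    q_bar = float(q.mean())
    n = n_p + n_q
    r_bar = (n_p * p_bar + n_q * q_bar) / n
    if n >= 3:
        if variance == "pooled":
            s2 = pooled_variance(p, q)
        elif variance == "total":
            s2 = total_variance(p, q)
        else:
            raise ValueError(f"unknown variance mode {variance!r}")
    else:
        s2 = math.nan
    return GeneBurden(
        gene=gene.gene,
        case_counts=p,
        control_counts=q,
        case_mean=p_bar,
        control_mean=q_bar,
        grand_mean=r_bar,
        pooled_variance=s2,
        n_case=n_p,
        n_control=n_q,
        n_total=n,
    )


def pooled_variance(case_counts: Sequence[float], control_counts: Sequence[float]) -> float:
    """Two-sample pooled variance with denominator N - 2."""
    p = np.asarray(case_counts, dtype=float)
    q = np.asarray(control_counts, dtype=float)
    if p.size < 1 or q.size < 1:
        raise ValueError("both groups must be non-empty")
    n = p.size + q.size
    if n < 3:
        raise ValueError(f"pooled variance needs N >= 3, got N = {n}")
    ssd = float(((p - p.mean()) ** 2).sum() + ((q - q.mean()) ** 2).sum())
    return ssd / (n - 2)


def total_variance(case_counts: Sequence[float], control_counts: Sequence[float]) -> float:
    """Sample variance of all counts around the grand mean, denominator N - 1."""
    allc = np.concatenate(
        [np.asarray(case_counts, dtype=float), np.asarray(control_counts, dtype=float)]
    )
    if allc.size < 2:
        raise ValueError("total variance needs N >= 2")
    return float(allc.var(ddof=1))


def t_g_statistic(burden: GeneBurden, n_rare_snps: int | None = None) -> GeneTestResult:
    """Evaluate T_G and its chi-square(1 df) p-value for one gene burden."""
    if burden.n_case < 1 or burden.n_control < 1:
        raise ValueError(f"{burden.gene}: need cases and controls")
    if burden.n_total < 3:
        raise ValueError(f"{burden.gene}: N >= 3 required for the pooled variance")
    s2 = burden.pooled_variance
    diff = burden.case_mean - burden.control_mean
    nr = n_rare_snps if n_rare_snps is not None else 0
    if s2 == 0.0:
        # Zero pooled variance: constant counts within each group.
        p_value = 1.0 if diff == 0.0 else math.nan
        return GeneTestResult(
            gene=burden.gene,
            t_g=math.nan,
            p_value=p_value,
            n_rare_snps=nr,
            degenerate=True,
            n_case=burden.n_case,
            n_control=burden.n_control,
            case_mean=burden.case_mean,
            control_mean=burden.control_mean,
            pooled_var=s2,
        )
    t_g = diff**2 / (s2 * (1.0 / burden.n_case + 1.0 / burden.n_control))
    p_value = float(stats.chi2.sf(t_g, df=1))
    return GeneTestResult(
        gene=burden.gene,
        t_g=float(t_g),
        p_value=max(p_value, np.nextafter(0, 1)),
        n_rare_snps=nr,
        degenerate=False,
        n_case=burden.n_case,
        n_control=burden.n_control,
        case_mean=burden.case_mean,
        control_mean=burden.control_mean,
        pooled_var=s2,
    )


def t_g_from_counts(
    case: np.ndarray, control: np.ndarray, variance: str = "pooled"
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized T_G over many genes at once.

    ``case`` is a (G, n_P) array of burden counts and ``control`` a
    (G, n_Q) array; returns arrays of T_G values and chi-square(1 df)
    p-values of length G.  Degenerate rows (zero variance) get ``nan``
    statistics, with p = 1 when the group means also agree.
    """
    case = np.atleast_2d(np.asarray(case, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    n_p, n_q = case.shape[1], control.shape[1]
    n = n_p + n_q
    if n < 3:
        raise ValueError("N >= 3 required")
    p_bar = case.mean(axis=1)
    q_bar = control.mean(axis=1)
    ssd = ((case - p_bar[:, None]) ** 2).sum(axis=1) + ((control - q_bar[:, None]) ** 2).sum(axis=1)
    if variance == "pooled":
        s2 = ssd / (n - 2)
    elif variance == "total":
        allc = np.concatenate([case, control], axis=1)
        s2 = allc.var(axis=1, ddof=1)
    else:
        raise ValueError(f"unknown variance mode {variance!r}")
    diff = p_bar - q_bar
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff**2 / (s2 * (1.0 / n_p + 1.0 / n_q))
    degenerate = s2 == 0.0
    t = np.where(degenerate, np.nan, t)
    p = np.full_like(t, np.nan)
    ok = ~degenerate
    p[ok] = stats.chi2.sf(t[ok], df=1)
    p[degenerate & (diff == 0.0)] = 1.0
    return t, p


def scan_genes(
    genotypes: GenotypeMatrix,
    variants: Sequence[VariantRecord],
    genes: Sequence[GeneRegion],
    phenotype: PhenotypeVector,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    count_mode: str = "dosage",
    variance: str = "pooled",
    external_mafs: Mapping[str, float] | None = None,
) -> list[GeneTestResult]:
    """Run the burden test over every gene.

    MAFs are estimated from the full analyzed sample unless
    ``external_mafs`` supplies per-variant population frequencies.  Returns
    one result per input gene, in input order, including degenerate genes.
    """
    if genotypes.sample_ids != phenotype.sample_ids:
        geno = set(genotypes.sample_ids)
        phen = set(phenotype.sample_ids)
        only_g = sorted(geno - phen)[:5]
        only_p = sorted(phen - geno)[:5]
        if only_g or only_p:
            raise ValueError(
                f"sample IDs differ between genotypes and phenotype "
                f"(genotype-only: {only_g}, phenotype-only: {only_p})"
            )
        raise ValueError("genotype and phenotype samples are ordered differently")
    if phenotype.n_case < 2 or phenotype.n_control < 2:
        raise ValueError("need at least 2 cases and 2 controls")

    # Attach MAFs: externally supplied per variant, else folded sample MAF.
    with_maf: list[VariantRecord] = []
    for v in variants:
        if external_mafs is not None and v.variant_id in external_mafs:
            maf = external_mafs[v.variant_id]
        elif v.maf is not None:
            maf = v.maf
        else:
            col = genotypes.dosage[:, genotypes.columns([v.variant_id])[0]]
            maf = compute_maf(col)
        with_maf.append(
            VariantRecord(v.variant_id, v.chrom, v.pos, v.ref_allele, v.alt_allele, maf)
        )

    rare_ids = {v.variant_id for v in select_rare(with_maf, maf_threshold)}
    gene_to_variants = assign_variants_to_genes(with_maf, genes)

    results = []
    for g in genes:
        vids = gene_to_variants[g.gene]
        rare = [v for v in vids if v in rare_ids]
        burden = burden_counts(g, rare, genotypes, phenotype, count_mode, variance)
        res = t_g_statistic(burden, n_rare_snps=len(rare))
        res.chrom = g.chrom
        res.n_snps = len(vids)
        res.n_rare_snps = len(rare)
        results.append(res)
    return results
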