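"""Readers and writers for the file formats the tool exchanges.

VCF (v4.x, diploid GT) carries genotypes; gene regions arrive as BED
(0-based half-open, converted on read to the 1-based inclusive convention
used internally) or as a TSV with header ``gene chrom start end`` already
1-based inclusive; phenotypes are a TSV with header ``sample status``
(0 = control, 1 = case).  Results go out as a TSV with one row per gene.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import (
    GeneRegion,
    GeneTestResult,
    GenotypeMatrix,
    PhenotypeVector,
    VariantRecord,
)
from .simulate import SimConfig

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_gene_table",
    "write_gene_table",
    "read_phenotype",
    "write_phenotype",
    "write_results",
    "read_results",
    "write_truth",
    "read_truth",
    "write_manifest",
    "load_sim_config",
]

RESULT_COLUMNS = [
    "gene", "chrom", "n_snps", "n_rare_snps", "n_case", "n_control",
    "case_mean", "control_mean", "pooled_var", "t_g", "p_value", "degenerate",
]


def read_vcf(path: str | Path, multiallelic: str = "skip") -> tuple[list[VariantRecord], GenotypeMatrix]:
    """Load a VCF into variant records and an alt-allele dosage matrix.

    GT calls map 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing.
    Multi-allelic records are skipped with a warning (``multiallelic='skip'``)
    or decomposed into one pseudo-variant per alternate allele (``'split'``,
    counting only that allele).  MAFs are left unset; the scan computes them
    from the sample unless population values are supplied.
    """
    if multiallelic not in ("skip", "split"):
        raise ValueError(f"multiallelic must be 'skip' or 'split', got {multiallelic!r}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF contains no samples")

    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        alts = rec.ALT
        if len(alts) == 0:
            continue
        gts = np.array(rec.genotypes, dtype=object)
        alleles = np.array([[g[0], g[1]] for g in gts], dtype=float)
        alleles[alleles < 0] = np.nan
        if len(alts) > 1:
            if multiallelic == "skip":
                warnings.warn(
                    f"{path}: skipping multi-allelic record {rec.CHROM}:{rec.POS}",
                    stacklevel=2,
                )
                continue
            for k, alt in enumerate(alts, start=1):
                dose = np.nansum(alleles == k, axis=1).astype(float)
                dose[np.isnan(alleles).all(axis=1)] = np.nan
                vid = rec.ID if rec.ID else f"{rec.CHROM}_{rec.POS}"
                variants.append(
                    VariantRecord(f"{vid}_alt{k}", rec.CHROM, rec.POS, rec.REF, alt)
                )
                rows.append(dose)
            continue
        dose = (alleles == 1).sum(axis=1).astype(float)
        dose[np.isnan(alleles).any(axis=1)] = np.nan
        vid = rec.ID if rec.ID else f"{rec.CHROM}_{rec.POS}"
        variants.append(VariantRecord(vid, rec.CHROM, rec.POS, rec.REF, alts[0]))
        rows.append(dose)

    dosage = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    matrix = GenotypeMatrix(samples, [v.variant_id for v in variants], dosage)
    return variants, matrix


def write_vcf(path: str | Path, variants: Sequence[VariantRecord], genotypes: GenotypeMatrix) -> None:
    """Write a minimal plain-text VCF v4.2 with GT-only genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = []
        for v in variants:
            if v.chrom not in chroms:
                chroms.append(v.chrom)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for v in variants:
            col = genotypes.dosage[:, genotypes.columns([v.variant_id])[0]]
            gts = "\t".join(
                "./." if math.isnan(d) else gt_map[d] for d in col
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref_allele}\t"
                f"{v.alt_allele}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_gene_table(path: str | Path, fmt: str = "tsv") -> list[GeneRegion]:
    """Read gene regions from BED or TSV.

    BED rows (chrom, start, end, name; 0-based half-open) are converted to
    1-based inclusive coordinates: start + 1, end unchanged.  TSV rows with
    header ``gene chrom start end`` are taken as already 1-based inclusive.
    """
    if fmt == "bed":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "gene"], usecols=range(4),
        )
        regions = []
        for i, row in enumerate(df.itertuples(index=False), start=1):
            start1, end1 = int(row.start) + 1, int(row.end)
            if start1 > end1:
                raise ValueError(f"{path} row {i}: empty or inverted BED interval "
                                 f"({row.start}, {row.end})")
            regions.append(GeneRegion(str(row.gene), str(row.chrom), start1, end1))
        return regions
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        required = {"gene", "chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: gene TSV needs columns {sorted(required)}")
        regions = []
        for i, row in enumerate(df.itertuples(index=False), start=1):
            if int(row.start) > int(row.end):
                raise ValueError(f"{path} row {i}: start > end")
            regions.append(GeneRegion(str(row.gene), str(row.chrom), int(row.start), int(row.end)))
        return regions
    raise ValueError(f"unknown gene table format {fmt!r}")


def write_gene_table(path: str | Path, genes: Sequence[GeneRegion]) -> None:
    pd.DataFrame(
        [(g.gene, g.chrom, g.start, g.end) for g in genes],
        columns=["gene", "chrom", "start", "end"],
    ).to_csv(path, sep="\t", index=False)


def read_phenotype(path: str | Path) -> PhenotypeVector:
    """TSV with header ``sample status``; status 1 = case, 0 = control."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if not {"sample", "status"}.issubset(df.columns):
        raise ValueError(f"{path}: phenotype TSV needs columns 'sample' and 'status'")
    if len(df) == 0:
        raise ValueError(f"{path}: phenotype file has no samples")
    bad = df[~df["status"].isin([0, 1])]
    if len(bad):
        raise ValueError(f"{path}: status must be 0 or 1; offending rows: "
                         f"{bad['sample'].tolist()[:5]}")
    if df["sample"].duplicated().any():
        dupes = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"{path}: duplicate sample IDs: {dupes[:5]}")
    return PhenotypeVector(df["sample"].tolist(), df["status"].to_numpy() == 1)


def write_phenotype(path: str | Path, phenotype: PhenotypeVector) -> None:
    pd.DataFrame(
        {"sample": phenotype.sample_ids, "status": phenotype.is_case.astype(int)}
    ).to_csv(path, sep="\t", index=False)


def write_results(path: str | Path, results: Sequence[GeneTestResult]) -> None:
    """Per-gene results TSV; p-values in full-precision scientific notation."""
    rows = []
    for r in results:
        rows.append({
            "gene": r.gene, "chrom": r.chrom, "n_snps": r.n_snps,
            "n_rare_snps": r.n_rare_snps, "n_case": r.n_case,
            "n_control": r.n_control, "case_mean": r.case_mean,
            "control_mean": r.control_mean, "pooled_var": r.pooled_var,
            "t_g": r.t_g, "p_value": r.p_value, "degenerate": int(r.degenerate),
        })
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_results(path: str | Path) -> list[GeneTestResult]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(GeneTestResult(
            gene=str(row.gene), t_g=float(row.t_g), p_value=float(row.p_value),
            n_rare_snps=int(row.n_rare_snps), degenerate=bool(row.degenerate),
            chrom=str(row.chrom), n_snps=int(row.n_snps), n_case=int(row.n_case),
            n_control=int(row.n_control), case_mean=float(row.case_mean),
            control_mean=float(row.control_mean), pooled_var=float(row.pooled_var),
        ))
    return out


def write_truth(
    path: str | Path,
    genes: Sequence[GeneRegion],
    causal_genes: set[str],
    n_causal_snps: dict[str, int] | None = None,
) -> None:
    """Truth labels: ``gene is_causal n_causal_snps`` per gene."""
    counts = n_causal_snps or {}
    pd.DataFrame({
        "gene": [g.gene for g in genes],
        "is_causal": [int(g.gene in causal_genes) for g in genes],
        "n_causal_snps": [counts.get(g.gene, 0) for g in genes],
    }).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> set[str]:
    df = pd.read_csv(path, sep="\t")
    return set(df.loc[df["is_causal"] == 1, "gene"].astype(str))


def write_manifest(path: str | Path, config: SimConfig | dict, extra: dict | None = None) -> None:
    """Run manifest: full config, seeds, and a config hash for reproducibility."""
    cfg = asdict(config) if isinstance(config, SimConfig) else dict(config)
    payload = {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()}
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]
    doc = {"config": payload, "config_hash": digest}
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_sim_config(path: str | Path) -> SimConfig:
    """Build a SimConfig from a YAML mapping of field names to values."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "trait_weights" in raw:
        raw["trait_weights"] = tuple(raw["trait_weights"])
    return SimConfig(**raw)
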