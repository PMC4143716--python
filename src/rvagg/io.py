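"""Readers and writers for the standard formats.

Supported inputs: VCF v4.x (biallelic SNVs, GT fields), gene maps as BED
(0-based half-open, 4th column = gene id) or TSV (variant_id, gene_id;
1-based positions where positions appear), phenotype TSV (sample_id, status),
and a plain genotype-matrix TSV dialect: header row of variant ids, first
column the sample id, cells in {0,1,2}.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .model import GenotypeMatrix, PhenotypeVector, compute_maf, orient_minor_allele

logger = logging.getLogger(__name__)

__all__ = [
    "read_region_map",
    "read_vcf",
    "read_phenotype",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "write_variant_summary",
]


class RegionMap:
    """Assigns variants to genes, from BED intervals or an explicit TSV."""

    def __init__(self, by_id: dict[str, str] | None = None, trees: dict[str, IntervalTree] | None = None):
        self.by_id = by_id or {}
        self.trees = trees or {}

    def gene_for(self, variant_id: str, chrom: str, pos: int) -> str | None:
        """Gene for a variant, or None if it falls outside every region.

        ``pos`` is the 1-based VCF position; BED trees are queried at pos-1.
        """
        if variant_id in self.by_id:
            return self.by_id[variant_id]
        tree = self.trees.get(str(chrom))
        if tree is not None:
            hits = tree[pos - 1]
            if hits:
                # deterministic pick on overlap: lexicographically smallest gene
                return min(iv.data for iv in hits)
        return None


def read_region_map(path: str | Path) -> RegionMap:
    """Load a gene map: ``.bed`` -> interval lookup, otherwise a
    ``variant_id <tab> gene_id`` table (header optional)."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        trees: dict[str, IntervalTree] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"{path}:{ln}: BED gene map needs 4 columns (chrom start end gene)")
                chrom, start, end, gene = parts[0], int(parts[1]), int(parts[2]), parts[3]
                trees.setdefault(chrom, IntervalTree())[start:end] = gene
        return RegionMap(trees=trees)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 0] in ("variant_id", "variant"):
        df = df.iloc[1:]
    return RegionMap(by_id=dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def read_vcf(path: str | Path, region_map: str | Path | RegionMap) -> GenotypeMatrix:
    """Read biallelic SNVs from a VCF into an oriented minor-allele count matrix.

    Multiallelic records are skipped with a warning; missing genotypes are
    imputed as 0 copies and the per-variant missingness rate recorded.
    Variants outside every mapped region are dropped.  A load report (kept /
    dropped counts) is logged at INFO level.
    """
    from cyvcf2 import VCF

    if not isinstance(region_map, RegionMap):
        region_map = read_region_map(region_map)

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicated sample ids in VCF header")
    n = len(sample_ids)

    cols, meta = [], []
    n_multi = n_unmapped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            logger.warning("skipping multiallelic record at %s:%d", var.CHROM, var.POS)
            continue
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}"
        gene = region_map.gene_for(vid, var.CHROM, var.POS)
        if gene is None:
            n_unmapped += 1
            continue
        gt = np.asarray(var.gt_types, dtype=np.int16)  # 0/1/2 copies of ALT, 3 = missing
        missing = gt == 3
        gt[missing] = 0
        oriented, _ = orient_minor_allele(gt)
        cols.append(oriented)
        meta.append(
            (vid, gene, str(var.CHROM), int(var.POS), compute_maf(oriented, n), missing.mean())
        )
    counts = np.column_stack(cols) if cols else np.empty((n, 0), dtype=np.int16)
    variants = pd.DataFrame(
        meta, columns=["variant_id", "gene_id", "chrom", "pos", "maf", "missingness"]
    )
    logger.info(
        "VCF load: kept %d variants, skipped %d multiallelic, dropped %d unmapped",
        len(meta), n_multi, n_unmapped,
    )
    return GenotypeMatrix(sample_ids, counts, variants)


def read_phenotype(path: str | Path) -> PhenotypeVector:
    """Phenotype TSV: sample_id <tab> status (0 = control, 1 = case)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 1] in ("status", "phenotype"):
        df = df.iloc[1:]
    status = df.iloc[:, 1].astype(int).to_numpy()
    return PhenotypeVector(list(df.iloc[:, 0]), status)


def read_genotype_tsv(path: str | Path, region_map: str | Path | RegionMap) -> GenotypeMatrix:
    """Read the plain matrix dialect and assign genes from a region map."""
    if not isinstance(region_map, RegionMap):
        region_map = read_region_map(region_map)
    df = pd.read_csv(path, sep="\t", index_col=0)
    sample_ids = [str(s) for s in df.index]
    variant_ids = [str(v) for v in df.columns]
    genes, keep = [], []
    for j, vid in enumerate(variant_ids):
        gene = region_map.gene_for(vid, ".", 0)
        if gene is not None:
            genes.append(gene)
            keep.append(j)
    counts = df.to_numpy(dtype=np.int16)[:, keep]
    return GenotypeMatrix.from_counts(
        sample_ids, counts, [variant_ids[j] for j in keep], genes
    )


def write_genotype_tsv(genotypes: GenotypeMatrix, path: str | Path,
                       gene_map_path: str | Path | None = None) -> None:
    """Write the plain matrix dialect; optionally the matching gene-map TSV."""
    df = pd.DataFrame(
        genotypes.counts,
        index=pd.Index(genotypes.sample_ids, name="sample_id"),
        columns=list(genotypes.variants["variant_id"]),
    )
    df.to_csv(path, sep="\t")
    if gene_map_path is not None:
        genotypes.variants[["variant_id", "gene_id"]].to_csv(
            gene_map_path, sep="\t", header=False, index=False
        )


def write_variant_summary(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Genotype summary TSV: variant_id, gene_id, maf, missingness."""
    genotypes.variants[["variant_id", "gene_id", "maf", "missingness"]].to_csv(
        path, sep="\t", index=False
    )
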