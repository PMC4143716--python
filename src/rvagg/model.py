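"""Core data model: genotype matrices, phenotypes, MAF computation and filtering.

Genotypes are stored as a dense ``(n_samples, n_variants)`` integer array of
minor-allele copy counts (0/1/2) with a per-variant metadata table.  All
statistics downstream assume counts are oriented to the *minor* allele of the
combined case-control sample, so orientation happens once, at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "PhenotypeVector",
    "compute_maf",
    "orient_minor_allele",
    "maf_filter",
]


@dataclass
class VariantRecord:
    """One biallelic SNV with its oriented minor-allele counts.

    ``minor_allele_counts`` holds one entry per sample, each in {0, 1, 2};
    ``empirical_maf`` is the combined-sample minor allele frequency, always
    at most 0.5 after orientation.
    """

    variant_id: str
    gene_id: str
    chrom: str
    pos: int
    minor_allele_counts: np.ndarray
    empirical_maf: float
    missingness: float = 0.0


def compute_maf(counts: np.ndarray, n_samples: int) -> float:
    """Empirical allele frequency of the counted allele: sum(counts) / (2n).

    Counts must already be oriented to the minor allele for the result to be
    a MAF (i.e. <= 0.5).
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    return float(np.sum(counts)) / (2.0 * n_samples)


def orient_minor_allele(counts: np.ndarray) -> tuple[np.ndarray, bool]:
    """Flip a count vector (c -> 2-c) if the counted allele is the major one.

    Returns ``(oriented_counts, flipped)``.  At frequency exactly 0.5 the
    original (ALT) allele stays counted, so the operation is idempotent and
    deterministic.
    """
    counts = np.asarray(counts, dtype=np.int16)
    n = counts.shape[0]
    if n == 0:
        return counts, False
    freq = counts.sum() / (2.0 * n)
    if freq > 0.5:
        return (2 - counts).astype(np.int16), True
    return counts, False


class GenotypeMatrix:
    """Samples x variants minor-allele count matrix with a gene index.

    Parameters
    ----------
    sample_ids
        Ordered sample identifiers (rows).
    counts
        ``(n_samples, n_variants)`` array of values in {0, 1, 2}, oriented to
        the minor allele.
    variants
        DataFrame with columns ``variant_id, gene_id, chrom, pos, maf,
        missingness`` (one row per column of ``counts``).
    """

    def __init__(self, sample_ids, counts: np.ndarray, variants: pd.DataFrame):
        sample_ids = list(sample_ids)
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicated sample ids")
        counts = np.asarray(counts, dtype=np.int16)
        if counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional")
        if counts.shape[0] != len(sample_ids):
            raise ValueError("counts rows must match number of sample ids")
        if counts.shape[1] != len(variants):
            raise ValueError("counts columns must match variant table")
        if counts.size and (counts.min() < 0 or counts.max() > 2):
            raise ValueError("genotype counts must lie in {0,1,2}")
        self.sample_ids = sample_ids
        self.counts = counts
        self.variants = variants.reset_index(drop=True)
        self._build_gene_index()

    def _build_gene_index(self) -> None:
        idx: dict[str, list[int]] = {}
        for j, g in enumerate(self.variants["gene_id"]):
            idx.setdefault(g, []).append(j)
        self.gene_index = {g: np.asarray(v, dtype=np.intp) for g, v in idx.items()}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return self.counts.shape[1]

    @property
    def genes(self) -> list[str]:
        return list(self.gene_index)

    def gene_slice(self, gene_id: str) -> "GenotypeMatrix":
        """Restriction of the matrix to one gene's variants."""
        cols = self.gene_index.get(gene_id)
        if cols is None:
            raise KeyError(f"unknown gene: {gene_id}")
        return GenotypeMatrix(
            self.sample_ids, self.counts[:, cols], self.variants.iloc[cols]
        )

    def variant_records(self):
        """Iterate variants as :class:`VariantRecord` objects."""
        for j, row in self.variants.iterrows():
            yield VariantRecord(
                variant_id=row["variant_id"],
                gene_id=row["gene_id"],
                chrom=str(row.get("chrom", ".")),
                pos=int(row.get("pos", 0)),
                minor_allele_counts=self.counts[:, j],
                empirical_maf=float(row["maf"]),
                missingness=float(row.get("missingness", 0.0)),
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
            and list(self.variants["variant_id"]) == list(other.variants["variant_id"])
            and list(self.variants["gene_id"]) == list(other.variants["gene_id"])
        )

    @classmethod
    def from_counts(cls, sample_ids, counts, variant_ids, gene_ids, chrom=None, pos=None):
        """Build a matrix from raw arrays, orienting each variant and
        computing its empirical MAF."""
        counts = np.asarray(counts, dtype=np.int16)
        n = counts.shape[0]
        oriented = np.empty_like(counts)
        mafs = np.empty(counts.shape[1])
        for j in range(counts.shape[1]):
            c, _ = orient_minor_allele(counts[:, j])
            oriented[:, j] = c
            mafs[j] = compute_maf(c, n)
        variants = pd.DataFrame(
            {
                "variant_id": list(variant_ids),
                "gene_id": list(gene_ids),
                "chrom": chrom if chrom is not None else ["."] * counts.shape[1],
                "pos": pos if pos is not None else np.zeros(counts.shape[1], dtype=int),
                "maf": mafs,
                "missingness": np.zeros(counts.shape[1]),
            }
        )
        return cls(sample_ids, oriented, variants)


@dataclass
class PhenotypeVector:
    """Binary case/control labels aligned to a genotype matrix by sample id."""

    sample_ids: list[str]
    status: np.ndarray
    n_case: int = field(init=False)
    n_control: int = field(init=False)

    def __post_init__(self):
        self.status = np.asarray(self.status, dtype=np.int8)
        if self.status.ndim != 1 or len(self.status) != len(self.sample_ids):
            raise ValueError("status must be 1-d and match sample ids")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status entries must be 0 (control) or 1 (case)")
        self.n_case = int(self.status.sum())
        self.n_control = len(self.status) - self.n_case

    def aligned_to(self, genotypes: GenotypeMatrix) -> "PhenotypeVector":
        """Reorder to the genotype matrix's sample order (by id, not position)."""
        if self.sample_ids == genotypes.sample_ids:
            return self
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in genotypes.sample_ids if s not in lookup]
        extra = [s for s in self.sample_ids if s not in set(genotypes.sample_ids)]
        if missing or extra:
            raise ValueError(
                "phenotype/genotype sample mismatch; "
                f"missing from phenotype: {missing[:5]}, unmatched: {extra[:5]}"
            )
        order = [lookup[s] for s in genotypes.sample_ids]
        return PhenotypeVector(list(genotypes.sample_ids), self.status[order])


def maf_filter(genotypes: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Retain variants with 0 < empirical MAF < ``threshold`` (strict).

    Monomorphic variants carry no case-control information and are dropped;
    the gene index is rebuilt.  An empty result is legal.
    """
    if not (0.0 < threshold <= 0.5):
        raise ValueError("threshold must lie in (0, 0.5]")
    maf = genotypes.variants["maf"].to_numpy()
    keep = np.flatnonzero((maf > 0.0) & (maf < threshold))
    return GenotypeMatrix(
        genotypes.sample_ids,
        genotypes.counts[:, keep],
        genotypes.variants.iloc[keep],
    )
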