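import numpy as np
import pytest

from rvagg import GenotypeMatrix, PhenotypeVector


def make_matrix(counts, gene_ids=None, sample_ids=None, variant_ids=None):
    """GenotypeMatrix from a raw (n_samples, n_variants) count array."""
    counts = np.asarray(counts)
    n, v = counts.shape
    return GenotypeMatrix.from_counts(
        sample_ids or [f"s{i}" for i in range(n)],
        counts,
        variant_ids or [f"v{j}" for j in range(v)],
        gene_ids or ["G1"] * v,
    )


def make_phenotype(status, sample_ids=None):
    status = np.asarray(status)
    return PhenotypeVector(sample_ids or [f"s{i}" for i in range(len(status))], status)


@pytest.fixture
def rng():
    return np.random.default_rng(20240617)


TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\tD\tE
1\t100\trs1\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\t0/0\t1/1
1\t200\trs2\tG\tC\t.\tPASS\t.\tGT\t1/1\t1/1\t1/1\t0/1\t1/1
1\t300\trs3\tC\tG,A\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\t0/0\t0/0
1\t400\trs4\tT\tA\t.\tPASS\t.\tGT\t./.\t0/1\t0/0\t0/0\t0/0
"""

TOY_GENE_MAP = "rs1\tGENE1\nrs2\tGENE1\nrs3\tGENE2\nrs4\tGENE2\n"


@pytest.fixture
def toy_vcf(tmp_path):
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(TOY_VCF)
    gene_map = tmp_path / "genes.tsv"
    gene_map.write_text(TOY_GENE_MAP)
    return vcf, gene_map
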