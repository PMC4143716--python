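"""Permutation inference: p-values, the Bernoulli(0.5) phenotype-resampling
null, and per-gene / per-cohort orchestration of the six tests.

P-values use the add-one estimator p = (1 + #{permuted >= observed}) /
(n_permutations + 1), which is a valid p-value under exchangeability and is
never 0.  Within each permutation the data-adaptive pieces are recomputed:
the variable-threshold test re-maximizes over thresholds and the
replication-based statistics recompute tau.  All six tests reject in the
upper tail (for C-alpha this targets the overdispersion alternative; T can
be negative under the null).  The six methods share one permutation stream
per gene, which removes between-method Monte Carlo noise when comparing them.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import comparators, rbs
from .model import GenotypeMatrix, PhenotypeVector, maf_filter

__all__ = [
    "METHODS",
    "TestResult",
    "AnalysisConfig",
    "gene_seed",
    "permutation_pvalue",
    "null_resample_phenotype",
    "analyze_gene",
    "analyze_cohort",
]

METHODS = ("s_tau", "s_comb", "s_max", "c_alpha", "vt", "skat")

_TOL = 1e-9  # relative tie tolerance when counting permuted >= observed


@dataclass
class TestResult:
    gene_id: str
    method: str
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    degenerate_flag: bool = False
    selected_threshold: float = float("nan")


@dataclass
class AnalysisConfig:
    """Knobs of a cohort analysis.

    alpha: per-gene significance level (no multiple-testing correction by
    default; set ``bonferroni=True`` to divide alpha by the gene count).
    maf_max: variants with empirical MAF >= this are excluded (strict <).
    """

    alpha: float = 0.05
    maf_max: float = 0.05
    n_permutations: int = 999
    seed: int = 0
    methods: tuple[str, ...] = METHODS
    bonferroni: bool = False

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("need at least 1 permutation")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def gene_seed(seed: int, gene_id: str) -> int:
    """Deterministic child seed for one gene (stable across runs, < 2^31)."""
    return (int(seed) * 2654435761 + zlib.crc32(gene_id.encode())) % (2**31)


def _permutation_labels(status: np.ndarray, n_permutations: int, rng: np.random.Generator) -> np.ndarray:
    """(n_permutations + 1, n) label matrix: observed labels first, then
    uniform permutations preserving the case/control counts."""
    perms = rng.permuted(
        np.tile(status, (n_permutations, 1)), axis=1
    )
    return np.vstack([status[None, :], perms])


def _empirical_p(observed: float, permuted: np.ndarray) -> float:
    tol = _TOL * max(1.0, abs(observed))
    exceed = int(np.count_nonzero(permuted >= observed - tol))
    return (1 + exceed) / (len(permuted) + 1)


def permutation_pvalue(
    stat_fn,
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeVector,
    n_permutations: int,
    seed: int,
    gene_id: str = "",
    method: str | None = None,
) -> TestResult:
    """Generic permutation p-value for an arbitrary gene-level statistic.

    ``stat_fn(counts, status)`` must be deterministic and return either a
    float or a ``(float, degenerate_flag)`` pair.  A degenerate observed
    statistic yields p = 1 with the flag propagated.
    """
    phenotype = phenotype.aligned_to(genotypes)
    rng = np.random.default_rng(seed)
    labels = _permutation_labels(phenotype.status, n_permutations, rng)

    def call(status):
        out = stat_fn(genotypes.counts, status)
        return out if isinstance(out, tuple) else (float(out), False)

    observed, degenerate = call(labels[0])
    name = method or getattr(stat_fn, "__name__", "custom")
    if degenerate:
        return TestResult(gene_id, name, observed, 1.0, n_permutations, seed, True)
    permuted = np.array([call(labels[b])[0] for b in range(1, n_permutations + 1)])
    return TestResult(
        gene_id, name, observed, _empirical_p(observed, permuted), n_permutations, seed
    )


def null_resample_phenotype(
    phenotype: PhenotypeVector,
    seed: int | np.random.Generator,
    flip_prob: float = 0.5,
) -> PhenotypeVector:
    """Phenotype made independent of genotype by random label flips.

    Each sample's status is independently switched to the other group with
    probability ``flip_prob`` (0.5 by default, which makes the resampled
    labels independent fair coin flips regardless of the original labels).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flips = rng.random(len(phenotype.status)) < flip_prob
    status = np.where(flips, 1 - phenotype.status, phenotype.status)
    return PhenotypeVector(list(phenotype.sample_ids), status)


def _batch_statistics(gene: GenotypeMatrix, labels: np.ndarray, methods) -> dict[str, dict]:
    """All requested statistics over the shared label stack."""
    counts = gene.counts
    mafs = gene.variants["maf"].to_numpy(dtype=float)
    out: dict[str, dict] = {}
    rbs_methods = [m for m in methods if m in ("s_tau", "s_comb", "s_max")]
    if rbs_methods:
        batch = rbs.rbs_batch(counts, labels)
        for m in rbs_methods:
            out[m] = {"stat": batch[m], "degenerate": batch["degenerate"]}
    if "c_alpha" in methods:
        batch = comparators.c_alpha_batch(counts, labels)
        out["c_alpha"] = {"stat": batch["t_stat"], "degenerate": batch["degenerate"]}
    if "vt" in methods:
        batch = comparators.vt_batch(counts, mafs, labels)
        out["vt"] = {
            "stat": batch["z_max"],
            "degenerate": batch["degenerate"],
            "selected_threshold": batch["selected_threshold"],
        }
    if "skat" in methods:
        batch = comparators.skat_batch(counts, mafs, labels)
        out["skat"] = {"stat": batch["q_stat"], "degenerate": batch["degenerate"]}
    return out


def analyze_gene(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeVector,
    config: AnalysisConfig,
    gene_id: str | None = None,
    prefiltered: bool = False,
) -> list[TestResult]:
    """Run every requested test on one gene with a shared permutation stream.

    The gene slice is MAF-filtered first (strictly below ``config.maf_max``,
    monomorphic variants dropped); if nothing survives, every method returns
    a degenerate result with p = 1.
    """
    phenotype = phenotype.aligned_to(genotypes)
    if phenotype.n_case == 0 or phenotype.n_control == 0:
        raise ValueError("need at least one case and one control")
    gid = gene_id if gene_id is not None else (genotypes.genes[0] if genotypes.genes else "")
    gene = genotypes if prefiltered else maf_filter(genotypes, config.maf_max)
    seed = gene_seed(config.seed, gid)
    B = config.n_permutations

    if gene.n_variants == 0:
        return [
            TestResult(gid, m, 0.0, 1.0, B, seed, True) for m in config.methods
        ]

    rng = np.random.default_rng(seed)
    labels = _permutation_labels(phenotype.status, B, rng).astype(np.float64)
    batches = _batch_statistics(gene, labels, config.methods)

    results = []
    for m in config.methods:
        b = batches[m]
        observed = float(b["stat"][0])
        degenerate = bool(b["degenerate"][0])
        sel = float(b["selected_threshold"][0]) if "selected_threshold" in b else float("nan")
        p = 1.0 if degenerate else _empirical_p(observed, b["stat"][1:])
        results.append(
            TestResult(gid, m, observed, p, B, seed, degenerate, sel)
        )
    return results


def analyze_cohort(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeVector,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Per-gene, per-method results table with a significance indicator.

    Columns: gene, method, statistic, p_value, significant, n_permutations,
    selected_threshold, degenerate_flag, seed.  Significance is assessed at
    ``config.alpha`` per gene (optionally Bonferroni-divided by gene count).
    """
    phenotype = phenotype.aligned_to(genotypes)
    filtered = maf_filter(genotypes, config.maf_max)
    genes = genotypes.genes  # keep genes that filtering empties: degenerate rows
    alpha = config.alpha / max(len(genes), 1) if config.bonferroni else config.alpha
    rows = []
    for gid in genes:
        if gid in filtered.gene_index:
            gene = filtered.gene_slice(gid)
            res = analyze_gene(gene, phenotype, config, gene_id=gid, prefiltered=True)
        else:
            res = [
                TestResult(gid, m, 0.0, 1.0, config.n_permutations,
                           gene_seed(config.seed, gid), True)
                for m in config.methods
            ]
        for r in res:
            rows.append(
                (r.gene_id, r.method, r.statistic, r.p_value, r.p_value <= alpha,
                 r.n_permutations, r.selected_threshold, r.degenerate_flag, r.seed)
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "method", "statistic", "p_value", "significant",
                 "n_permutations", "selected_threshold", "degenerate_flag", "seed"],
    )
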