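"""Synthetic case-control cohorts and the type-I-error / power protocol.

The generator emulates small sequencing studies of gene regions harbouring
rare variants: per gene a MAF spectrum is drawn from a rare-skewed Beta
distribution truncated below 0.05, genotypes follow Hardy-Weinberg
proportions (Binomial(2, maf), independent variants — no linkage
disequilibrium by default), and disease status follows a logistic model on
the causal minor-allele counts.  Cohorts are collected retrospectively:
individuals are drawn until exact case and control quotas are filled, so the
analyzed sample composition is fixed (55 cases / 48 controls by default).

Power and type-I error are estimated as the proportion of simulation
replicates in which each method's permutation p-value falls at or below
alpha (200 replicates by default).  For type-I error the phenotype is
replaced, per replicate, by the Bernoulli(0.5) label-flip resample, making it
independent of the genotypes while keeping the genotype data fixed across
replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .inference import AnalysisConfig, analyze_cohort, null_resample_phenotype
from .model import GenotypeMatrix, PhenotypeVector

__all__ = [
    "GeneArchitecture",
    "ArchitectureRanges",
    "CohortConfig",
    "signal_strength",
    "sample_architecture",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_cohort",
    "estimate_power",
    "estimate_type1",
    "method_average",
]

#: signal strengths above this fraction fall outside the regime the default
#: configuration targets (at most 9 causal among >= 200 variants)
SIGNAL_STRENGTH_BAND = 0.045


@dataclass
class GeneArchitecture:
    """True generative description of one gene region."""

    gene_id: str
    n_variants: int
    mafs: np.ndarray  # population MAFs, each in (0, 0.05)
    causal_indices: np.ndarray  # subset of variant indices
    effect_log_odds: np.ndarray  # one log-odds per causal variant (+ risk, - protective)

    def __post_init__(self):
        self.mafs = np.asarray(self.mafs, dtype=float)
        self.causal_indices = np.asarray(self.causal_indices, dtype=np.intp)
        self.effect_log_odds = np.asarray(self.effect_log_odds, dtype=float)
        if self.n_variants != len(self.mafs):
            raise ValueError("mafs length must equal n_variants")
        if len(self.causal_indices) != len(self.effect_log_odds):
            raise ValueError("one effect per causal variant required")
        if self.mafs.size and (self.mafs.min() <= 0 or self.mafs.max() >= 0.05):
            raise ValueError("population MAFs must lie strictly in (0, 0.05)")


def signal_strength(arch: GeneArchitecture) -> float:
    """Causal rare variants divided by total rare variants."""
    if arch.n_variants <= 0:
        raise ValueError("gene must contain variants")
    return len(arch.causal_indices) / arch.n_variants


@dataclass
class ArchitectureRanges:
    """Distributions from which gene architectures are drawn.

    Defaults target gene regions of 20-200 rare variants carrying 0-9 causal
    ones, a Beta(0.18, 9) MAF spectrum truncated to (1/(2e4), 0.05) — heavily
    skewed toward very rare alleles — and all-risk log-odds uniform on
    [0.5, 2.0].  Set ``risk_fraction`` below 1 for a risk/protective mix.
    """

    n_variants: tuple[int, int] = (20, 200)
    n_causal: tuple[int, int] = (0, 9)
    maf_beta: tuple[float, float] = (0.18, 9.0)
    maf_bounds: tuple[float, float] = (1.0 / 20_000.0, 0.05)
    effect_range: tuple[float, float] = (0.5, 2.0)
    risk_fraction: float = 1.0


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_architecture(
    ranges: ArchitectureRanges,
    seed: int | np.random.Generator,
    gene_id: str = "gene",
) -> GeneArchitecture:
    """Draw one gene architecture from the configured ranges."""
    rng = _as_rng(seed)
    lo_v, hi_v = ranges.n_variants
    lo_c, hi_c = ranges.n_causal
    if lo_v < 1 or lo_c > hi_v:
        raise ValueError("infeasible architecture ranges")
    n_variants = int(rng.integers(lo_v, hi_v + 1))
    n_causal = int(rng.integers(lo_c, min(hi_c, n_variants) + 1))
    a, b = ranges.maf_beta
    lo_m, hi_m = ranges.maf_bounds
    mafs = np.empty(n_variants)
    filled = 0
    while filled < n_variants:  # rejection sampling into the truncation window
        draw = rng.beta(a, b, size=2 * (n_variants - filled) + 8)
        draw = draw[(draw > lo_m) & (draw < hi_m)]
        take = min(len(draw), n_variants - filled)
        mafs[filled : filled + take] = draw[:take]
        filled += take
    causal = rng.choice(n_variants, size=n_causal, replace=False)
    mag = rng.uniform(*ranges.effect_range, size=n_causal)
    sign = np.where(rng.random(n_causal) < ranges.risk_fraction, 1.0, -1.0)
    arch = GeneArchitecture(gene_id, n_variants, mafs, causal, mag * sign)
    s = signal_strength(arch)
    if s > SIGNAL_STRENGTH_BAND:
        warnings.warn(
            f"{gene_id}: signal strength {s:.3f} exceeds the "
            f"{SIGNAL_STRENGTH_BAND:.1%} design band",
            stacklevel=2,
        )
    return arch


def simulate_genotypes(
    arch: GeneArchitecture, n_samples: int, seed: int | np.random.Generator
) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes for one gene: counts ~ Binomial(2, maf),
    independent across samples and variants."""
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = _as_rng(seed)
    counts = rng.binomial(2, arch.mafs[None, :], size=(n_samples, arch.n_variants))
    sample_ids = [f"S{i:05d}" for i in range(n_samples)]
    vids = [f"{arch.gene_id}_v{j}" for j in range(arch.n_variants)]
    return GenotypeMatrix.from_counts(
        sample_ids, counts, vids, [arch.gene_id] * arch.n_variants
    )


@dataclass
class CohortConfig:
    """Study design: cohort composition, gene architectures, disease model."""

    genes: list[GeneArchitecture] = field(default_factory=list)
    n_case: int = 55
    n_control: int = 48
    baseline_log_odds: float = 0.0
    replicates: int = 200
    seed: int = 0


def _case_probability(counts: np.ndarray, genes: list[GeneArchitecture],
                      gene_offsets: dict[str, int], baseline: float) -> np.ndarray:
    eta = np.full(counts.shape[0], baseline, dtype=float)
    for arch in genes:
        off = gene_offsets[arch.gene_id]
        if len(arch.causal_indices):
            eta += counts[:, off + arch.causal_indices] @ arch.effect_log_odds
    return expit(eta)


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    genes: list[GeneArchitecture],
    baseline_log_odds: float,
    seed: int | np.random.Generator,
) -> PhenotypeVector:
    """Disease status for given genotypes under the logistic model
    P(case) = logistic(baseline + sum over causal variants of effect x count)."""
    rng = _as_rng(seed)
    offsets = {g: int(cols[0]) for g, cols in genotypes.gene_index.items()}
    for arch in genes:
        if not np.all(np.isfinite(arch.effect_log_odds)):
            raise ValueError("effect sizes must be finite")
    p = _case_probability(genotypes.counts, genes, offsets, baseline_log_odds)
    status = (rng.random(len(p)) < p).astype(np.int8)
    return PhenotypeVector(list(genotypes.sample_ids), status)


def simulate_cohort(
    config: CohortConfig, seed: int | np.random.Generator, max_batches: int = 1000
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Retrospective sampling: draw individuals until the case and control
    quotas are both filled, then assemble the fixed-composition cohort.

    With a 50% baseline prevalence and no genetic effects the expected number
    of draws is about twice the cohort size.  Raises after ``max_batches``
    rounds if a quota is unattainable (e.g. case probability near 0).
    """
    rng = _as_rng(seed)
    n_needed = config.n_case + config.n_control
    batch = max(64, 2 * n_needed)
    case_rows, control_rows = [], []
    n_cases = n_controls = 0
    mafs_all = np.concatenate([g.mafs for g in config.genes])
    offsets, off = {}, 0
    for g in config.genes:
        offsets[g.gene_id] = off
        off += g.n_variants
    for _ in range(max_batches):
        counts = rng.binomial(2, mafs_all[None, :], size=(batch, len(mafs_all)))
        p = _case_probability(counts, config.genes, offsets, config.baseline_log_odds)
        is_case = rng.random(batch) < p
        if n_cases < config.n_case:
            take = counts[is_case][: config.n_case - n_cases]
            case_rows.append(take)
            n_cases += len(take)
        if n_controls < config.n_control:
            take = counts[~is_case][: config.n_control - n_controls]
            control_rows.append(take)
            n_controls += len(take)
        if n_cases >= config.n_case and n_controls >= config.n_control:
            break
    else:
        raise RuntimeError("case/control quotas unattainable under the disease model")

    counts = np.vstack([np.vstack(case_rows), np.vstack(control_rows)])
    status = np.concatenate(
        [np.ones(config.n_case, dtype=np.int8), np.zeros(config.n_control, dtype=np.int8)]
    )
    order = rng.permutation(n_needed)  # decouple sample order from status
    counts, status = counts[order], status[order]
    sample_ids = [f"S{i:05d}" for i in range(n_needed)]
    vids, gids = [], []
    for g in config.genes:
        vids.extend(f"{g.gene_id}_v{j}" for j in range(g.n_variants))
        gids.extend([g.gene_id] * g.n_variants)
    genotypes = GenotypeMatrix.from_counts(sample_ids, counts, vids, gids)
    return genotypes, PhenotypeVector(sample_ids, status)


def _replicate_seeds(seed: int, replicates: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(replicates)]


def _aggregate(frames: list[pd.DataFrame], replicates: int, alpha: float) -> pd.DataFrame:
    stacked = pd.concat(frames, ignore_index=True)
    grouped = (
        stacked.groupby(["gene", "method"], sort=True)["significant"]
        .agg(["mean", "count"])
        .reset_index()
    )
    power = grouped["mean"].to_numpy()
    return pd.DataFrame(
        {
            "gene_id": grouped["gene"],
            "method": grouped["method"],
            "power": power,
            "replicates": replicates,
            "alpha": alpha,
            "mc_se": np.sqrt(power * (1 - power) / replicates),
        }
    )


def estimate_power(config: CohortConfig, analysis: AnalysisConfig) -> pd.DataFrame:
    """Proportion of replicates in which each method flags each gene.

    Every replicate draws a fresh cohort (genotypes and phenotype) and runs
    the full analysis; rows carry Monte Carlo standard errors.
    """
    if config.replicates < 1:
        raise ValueError("need at least 1 replicate")
    seeds = _replicate_seeds(config.seed, config.replicates)
    frames = []
    for r, s in enumerate(seeds):
        genotypes, phenotype = simulate_cohort(config, s)
        rep_analysis = AnalysisConfig(
            alpha=analysis.alpha, maf_max=analysis.maf_max,
            n_permutations=analysis.n_permutations,
            seed=(analysis.seed * 1_000_003 + r) % (2**31),
            methods=analysis.methods, bonferroni=analysis.bonferroni,
        )
        frames.append(analyze_cohort(genotypes, phenotype, rep_analysis))
    return _aggregate(frames, config.replicates, analysis.alpha)


def estimate_type1(
    config: CohortConfig,
    analysis: AnalysisConfig,
    fresh_genotypes: bool = False,
) -> pd.DataFrame:
    """Empirical type-I error under the Bernoulli(0.5) label-flip null.

    The cohort is simulated once (genotypes fixed, as in a real study);
    each replicate replaces the phenotype with an independent label-flip
    resample and reruns every test, so any rejection is a false positive.
    Set ``fresh_genotypes=True`` to also redraw genotypes per replicate.
    """
    if config.replicates < 1:
        raise ValueError("need at least 1 replicate")
    seeds = _replicate_seeds(config.seed, config.replicates)
    genotypes, phenotype = simulate_cohort(config, config.seed)
    frames = []
    for r, s in enumerate(seeds):
        if fresh_genotypes:
            genotypes, phenotype = simulate_cohort(config, s)
        null_pheno = null_resample_phenotype(phenotype, s)
        rep_analysis = AnalysisConfig(
            alpha=analysis.alpha, maf_max=analysis.maf_max,
            n_permutations=analysis.n_permutations,
            seed=(analysis.seed * 1_000_003 + r) % (2**31),
            methods=analysis.methods, bonferroni=analysis.bonferroni,
        )
        frames.append(analyze_cohort(genotypes, null_pheno, rep_analysis))
    return _aggregate(frames, config.replicates, analysis.alpha)


def method_average(power_table: pd.DataFrame) -> pd.Series:
    """Gene-averaged rejection proportion per method."""
    return power_table.groupby("method")["power"].mean()


def null_calibration_study(
    seed: int,
    n_genes: int = 10,
    replicates: int = 200,
    n_permutations: int = 999,
    alpha: float = 0.05,
) -> tuple[CohortConfig, AnalysisConfig]:
    """The canonical type-I-error calibration design.

    One cohort of 103 unrelated individuals (55 cases / 48 controls) with
    ``n_genes`` null genes of 20-200 rare variants each (no causal variants);
    per replicate the phenotype is flip-resampled and every test is run with
    permutation p-values.  Feed the pair into :func:`estimate_type1`.
    """
    rng = np.random.default_rng(seed)
    ranges = ArchitectureRanges(n_causal=(0, 0))
    genes = [sample_architecture(ranges, rng, gene_id=f"NULL{i:02d}") for i in range(n_genes)]
    cohort = CohortConfig(genes=genes, n_case=55, n_control=48,
                          replicates=replicates, seed=int(seed) % (2**31))
    analysis = AnalysisConfig(alpha=alpha, maf_max=0.05,
                              n_permutations=n_permutations,
                              seed=int(seed) % (2**31))
    return cohort, analysis
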