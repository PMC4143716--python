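"""Comparator gene-level tests: variable-threshold burden, C-alpha, and a
SKAT-style weighted variance-component score test.

All three are reported with permutation p-values by the inference engine;
the analytic quantities exposed here (VT z-scores, the C-alpha z, a
moment-matched SKAT p-value) are diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import binom, chi2

from .model import GenotypeMatrix, PhenotypeVector

__all__ = [
    "VTResult",
    "CAlphaResult",
    "SkatResult",
    "vt_statistic",
    "c_alpha_statistic",
    "skat_statistic",
    "skat_asymptotic_pvalue",
    "vt_batch",
    "c_alpha_batch",
    "skat_batch",
]


# ---------------------------------------------------------------------------
# Variable-threshold burden test
# ---------------------------------------------------------------------------

@dataclass
class VTResult:
    z_max: float
    selected_threshold: float
    thresholds_tried: list[float]
    degenerate: bool = False


def _burden_by_threshold(counts: np.ndarray, mafs: np.ndarray, thresholds: np.ndarray):
    """Per-sample burden (sum of counts over variants with maf <= T) for each
    candidate threshold T; returns the (n_samples, n_thresholds) matrix."""
    include = mafs[None, :] <= thresholds[:, None]  # (T, V)
    return counts @ include.T.astype(np.float64)  # (n, T)


def vt_statistic(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeVector,
    thresholds: list[float] | None = None,
) -> VTResult:
    """Maximum standardized burden score over candidate MAF thresholds.

    For threshold T the score is the covariance between phenotype and the
    per-sample burden of variants with maf <= T, standardized as
    z = sum_s (y_s - ybar) b_s / sqrt(sum_s (y_s - ybar)^2 * Var(b)).
    Thresholds whose burden is constant across samples are skipped; if none
    remains the result is flagged degenerate (p reported as 1 upstream).
    The default candidate set is the distinct empirical MAFs of the gene's
    variants, so every variant defines one cutoff.
    """
    phenotype = phenotype.aligned_to(genotypes)
    mafs = genotypes.variants["maf"].to_numpy(dtype=float)
    if thresholds is None:
        thr = np.unique(mafs)
    else:
        thr = np.asarray(sorted(thresholds), dtype=float)
        if thr.size == 0 or thr.min() <= 0 or thr.max() > 0.5:
            raise ValueError("thresholds must be nonempty and in (0, 0.5]")
    y = phenotype.status.astype(float)
    z, valid = _vt_scores(genotypes.counts.astype(float), mafs, thr, y[None, :])
    z = z[0]
    if not valid.any():
        return VTResult(0.0, float("nan"), list(thr), degenerate=True)
    best = int(np.argmax(np.where(valid, z, -np.inf)))
    return VTResult(float(z[best]), float(thr[best]), list(thr))


def _vt_scores(counts, mafs, thresholds, labels):
    """Standardized burden z for every (label row, threshold); also the mask
    of thresholds with non-constant burden (label-independent)."""
    burden = _burden_by_threshold(counts, mafs, thresholds)  # (n, T)
    n = counts.shape[0]
    var_b = burden.var(axis=0)
    valid = var_b > 0
    q = labels[0].mean()
    ssy = ((labels[0] - q) ** 2).sum()
    denom = np.sqrt(ssy * np.where(valid, var_b, 1.0))
    yc = labels - labels.mean(axis=1, keepdims=True)
    num = yc @ burden  # (B, T)
    z = num / denom[None, :]
    z[:, ~valid] = -np.inf
    return z, valid


def vt_batch(counts: np.ndarray, mafs: np.ndarray, labels: np.ndarray,
             thresholds: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """z_max re-maximized over thresholds within every label assignment."""
    thr = np.unique(mafs) if thresholds is None else np.asarray(thresholds, float)
    labels = np.asarray(labels, dtype=np.float64)
    if counts.shape[1] == 0 or thr.size == 0:
        B = labels.shape[0]
        return {"z_max": np.zeros(B), "selected_threshold": np.full(B, np.nan),
                "degenerate": np.ones(B, dtype=bool)}
    z, valid = _vt_scores(counts.astype(np.float64), np.asarray(mafs, float), thr, labels)
    if not valid.any():
        B = labels.shape[0]
        return {"z_max": np.zeros(B), "selected_threshold": np.full(B, np.nan),
                "degenerate": np.ones(B, dtype=bool)}
    best = np.argmax(z, axis=1)
    return {
        "z_max": z[np.arange(z.shape[0]), best],
        "selected_threshold": thr[best],
        "degenerate": np.zeros(labels.shape[0], dtype=bool),
    }


# ---------------------------------------------------------------------------
# C-alpha
# ---------------------------------------------------------------------------

@dataclass
class CAlphaResult:
    t_stat: float
    variance_c: float
    z_score: float


def c_alpha_statistic(genotypes: GenotypeMatrix, phenotype: PhenotypeVector) -> CAlphaResult:
    """Binomial overdispersion statistic for the case/control copy split.

    With p0 the case fraction, y_i the copies of variant i in cases and n_i
    its total copies, T = sum_i [(y_i - n_i p0)^2 - n_i p0 (1 - p0)].  Under
    the null each y_i ~ Binomial(n_i, p0), so each term has mean 0; a mix of
    risk and protective variants inflates T.  variance_c sums the exact null
    variance of each term (by n_i group) and feeds the diagnostic z; the
    primary p-value is computed by permutation upstream.
    """
    phenotype = phenotype.aligned_to(genotypes)
    case = phenotype.status == 1
    n_i = genotypes.counts.sum(axis=0).astype(np.int64)
    if n_i.size == 0 or (n_i == 0).all():
        raise ValueError("no minor-allele copies in gene after filtering")
    y_i = genotypes.counts[case].sum(axis=0).astype(np.int64)
    p0 = phenotype.n_case / (phenotype.n_case + phenotype.n_control)
    terms = (y_i - n_i * p0) ** 2 - n_i * p0 * (1 - p0)
    t_stat = float(terms.sum())
    variance_c = 0.0
    for m in np.unique(n_i):
        if m == 0:
            continue
        count_m = int((n_i == m).sum())
        u = np.arange(m + 1)
        zvals = (u - m * p0) ** 2 - m * p0 * (1 - p0)
        pmf = binom.pmf(u, int(m), p0)
        variance_c += count_m * float((pmf * zvals**2).sum())
    z = t_stat / np.sqrt(variance_c) if variance_c > 0 else 0.0
    return CAlphaResult(t_stat, variance_c, float(z))


def c_alpha_batch(counts: np.ndarray, labels: np.ndarray) -> dict[str, np.ndarray]:
    """C-alpha T over a stack of label assignments."""
    labels = np.asarray(labels, dtype=np.float64)
    B = labels.shape[0]
    n_i = counts.sum(axis=0).astype(np.float64)
    if counts.shape[1] == 0 or (n_i == 0).all():
        return {"t_stat": np.zeros(B), "degenerate": np.ones(B, dtype=bool)}
    p0 = labels[0].mean()
    y = labels @ counts.astype(np.float64)  # (B, V) copies in cases
    terms = (y - n_i[None, :] * p0) ** 2 - (n_i * p0 * (1 - p0))[None, :]
    return {"t_stat": terms.sum(axis=1), "degenerate": np.zeros(B, dtype=bool)}


# ---------------------------------------------------------------------------
# SKAT-style weighted score test
# ---------------------------------------------------------------------------

@dataclass
class SkatResult:
    q_stat: float
    weights: np.ndarray
    beta_params: tuple[float, float] = (1.0, 25.0)
    degenerate: bool = False


def _beta_weights(mafs: np.ndarray, beta_params: tuple[float, float]) -> np.ndarray:
    a, b = beta_params
    return beta_dist.pdf(np.asarray(mafs, dtype=float), a, b)


def skat_statistic(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeVector,
    beta_params: tuple[float, float] = (1.0, 25.0),
) -> SkatResult:
    """Weighted variance-component score statistic Q = r' G W^2 G' r.

    r are residuals from the intercept-only null model (status minus case
    fraction) and W = diag(Beta(maf; a, b) density), defaults (1, 25), which
    up-weights the rarest variants.  Q >= 0, is 0 when residuals vanish, and
    is insensitive to the direction of each variant's effect.
    """
    phenotype = phenotype.aligned_to(genotypes)
    mafs = genotypes.variants["maf"].to_numpy(dtype=float)
    w = _beta_weights(mafs, beta_params)
    if genotypes.n_variants == 0 or (genotypes.counts.var(axis=0) == 0).all():
        return SkatResult(0.0, w, beta_params, degenerate=True)
    r = phenotype.status - phenotype.status.mean()
    score = r @ (genotypes.counts * w[None, :])
    return SkatResult(float((score**2).sum()), w, beta_params)


def skat_asymptotic_pvalue(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeVector,
    beta_params: tuple[float, float] = (1.0, 25.0),
) -> float:
    """Moment-matched (Satterthwaite) chi-square approximation to the null
    distribution of Q under label exchange; a large-sample diagnostic only."""
    phenotype = phenotype.aligned_to(genotypes)
    res = skat_statistic(genotypes, phenotype, beta_params)
    if res.degenerate:
        return 1.0
    n = genotypes.n_samples
    p0 = phenotype.n_case / n
    gw = genotypes.counts * res.weights[None, :]
    gw_c = gw - gw.mean(axis=0, keepdims=True)
    # K = centered Gram matrix; under exchangeable labels Var(r_s) ~ p0(1-p0)
    a_mat = gw_c.T @ gw_c  # (V, V); tr(PKP) = tr(A), tr((PKP)^2) = tr(A^2)
    v = p0 * (1 - p0)
    mean_q = v * np.trace(a_mat)
    var_q = 2 * v**2 * (a_mat * a_mat).sum()
    if var_q <= 0:
        return 1.0
    scale = var_q / (2 * mean_q)
    df = 2 * mean_q**2 / var_q
    return float(chi2.sf(res.q_stat / scale, df))


def skat_batch(counts: np.ndarray, mafs: np.ndarray, labels: np.ndarray,
               beta_params: tuple[float, float] = (1.0, 25.0)) -> dict[str, np.ndarray]:
    """Q over a stack of label assignments (residual mean is label-invariant
    under permutation, so centering uses each row's own mean)."""
    labels = np.asarray(labels, dtype=np.float64)
    B = labels.shape[0]
    if counts.shape[1] == 0 or (counts.var(axis=0) == 0).all():
        return {"q_stat": np.zeros(B), "degenerate": np.ones(B, dtype=bool)}
    w = _beta_weights(mafs, beta_params)
    gw = counts.astype(np.float64) * w[None, :]
    r = labels - labels.mean(axis=1, keepdims=True)
    score = r @ gw  # (B, V)
    return {"q_stat": (score**2).sum(axis=1), "degenerate": np.zeros(B, dtype=bool)}
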