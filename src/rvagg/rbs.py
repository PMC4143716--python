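"""The replication-based weighted sum statistic family.

For each rare variant in a gene, let k' be the minor-allele copies observed
in cases and k the copies in controls.  Variants are partitioned into a
case-excess group (k' > k) and a control-excess group (k' < k); ties carry no
directional evidence and contribute to neither.  Each oriented variant gets a
weight reflecting how surprising its case/control split is under the null:
with m = k' + k total copies and q the case fraction of the sample, the
weight is the negative log one-sided binomial tail

    w = -ln P(X >= k')   (case excess),   w = -ln P(X <= k')   (control excess),

with X ~ Binomial(m, q).  The group sums S+ (case excess) and S- (control
excess) combine into

    S_max  = max(S+, S-)
    S_comb = S+ + S-
    S_tau  = tau * S+ + (1 - tau) * S-,   tau = n+ / (n+ + n-),

where n+ and n- count the oriented variants in each group.  S_tau lets the
data weight the relative contribution of risk-like and protective-like
variants: tau -> 1 when nearly all oriented variants are case-enriched
(S_tau -> S+, the S_max-like extreme) and tau = 1/2 when the groups balance
(S_tau = S_comb / 2).

An alternative weight function may be supplied (e.g. constant 1, reducing the
sums to plain counts of oriented variants).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable

import numpy as np
from scipy.stats import binom

from .model import GenotypeMatrix, PhenotypeVector

__all__ = [
    "Orientation",
    "VariantCountPair",
    "RBSComponents",
    "partition_variants",
    "rbs_weight",
    "compute_rbs",
    "rbs_batch",
]


class Orientation(str, Enum):
    CASE_EXCESS = "case_excess"
    CONTROL_EXCESS = "control_excess"
    TIE = "tie"


@dataclass(frozen=True)
class VariantCountPair:
    """Minor-allele copy counts of one variant, split by phenotype group."""

    k_prime: int  # copies in cases
    k: int  # copies in controls

    @property
    def orientation(self) -> Orientation:
        if self.k_prime > self.k:
            return Orientation.CASE_EXCESS
        if self.k_prime < self.k:
            return Orientation.CONTROL_EXCESS
        return Orientation.TIE


@dataclass
class RBSComponents:
    """All replication-based statistics for one gene."""

    n_plus: int
    n_minus: int
    s_plus: float
    s_minus: float
    tau: float
    s_max: float
    s_comb: float
    s_tau: float
    degenerate: bool = False


def partition_variants(
    genotypes: GenotypeMatrix, phenotype: PhenotypeVector
) -> list[VariantCountPair]:
    """Per-variant (k', k) copy counts for one gene slice."""
    phenotype = phenotype.aligned_to(genotypes)
    if phenotype.n_case == 0 or phenotype.n_control == 0:
        raise ValueError("statistic undefined without both cases and controls")
    case = phenotype.status == 1
    k_prime = genotypes.counts[case].sum(axis=0)
    k = genotypes.counts[~case].sum(axis=0)
    return [VariantCountPair(int(a), int(b)) for a, b in zip(k_prime, k)]


def rbs_weight(pair: VariantCountPair, n_case: int, n_control: int) -> float:
    """Negative log one-sided binomial tail probability of the observed split."""
    if pair.orientation is Orientation.TIE:
        raise ValueError("tie variants carry no weight")
    m = pair.k_prime + pair.k
    if m == 0:
        raise ValueError("variant with no minor-allele copies")
    q = n_case / (n_case + n_control)
    if pair.orientation is Orientation.CASE_EXCESS:
        tail = binom.sf(pair.k_prime - 1, m, q)  # P(X >= k')
    else:
        tail = binom.cdf(pair.k_prime, m, q)  # P(X <= k')
    return float(-np.log(tail))


def _weight_tables(m_values: np.ndarray, q: float) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """For each distinct total copy count m, the weight of every possible k'.

    Returns m -> (w_plus[k'], w_minus[k']) arrays of length m+1; entries for
    splits of the opposite orientation are unused.
    """
    tables = {}
    for m in np.unique(m_values):
        m = int(m)
        ks = np.arange(m + 1)
        w_plus = -np.log(binom.sf(ks - 1, m, q))
        w_minus = -np.log(binom.cdf(ks, m, q))
        tables[m] = (w_plus, w_minus)
    return tables


def compute_rbs(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeVector,
    weight_fn: Callable[[VariantCountPair, int, int], float] | None = None,
) -> RBSComponents:
    """S+, S-, tau and the combined statistics for one gene.

    A gene with no oriented variants (every variant tied, or no variants at
    all) is flagged degenerate with all statistics 0 and tau = 0.5.
    """
    pairs = partition_variants(genotypes, phenotype)
    wf = weight_fn or rbs_weight
    s_plus = s_minus = 0.0
    n_plus = n_minus = 0
    for p in pairs:
        if p.orientation is Orientation.CASE_EXCESS:
            n_plus += 1
            s_plus += wf(p, phenotype.n_case, phenotype.n_control)
        elif p.orientation is Orientation.CONTROL_EXCESS:
            n_minus += 1
            s_minus += wf(p, phenotype.n_case, phenotype.n_control)
    n_oriented = n_plus + n_minus
    if n_oriented == 0:
        return RBSComponents(0, 0, 0.0, 0.0, 0.5, 0.0, 0.0, 0.0, degenerate=True)
    tau = n_plus / n_oriented
    return RBSComponents(
        n_plus=n_plus,
        n_minus=n_minus,
        s_plus=s_plus,
        s_minus=s_minus,
        tau=tau,
        s_max=max(s_plus, s_minus),
        s_comb=s_plus + s_minus,
        s_tau=tau * s_plus + (1.0 - tau) * s_minus,
    )


def rbs_batch(counts: np.ndarray, labels: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized RBS statistics over a stack of label assignments.

    Parameters
    ----------
    counts
        ``(n_samples, n_variants)`` oriented minor-allele counts for one gene.
    labels
        ``(n_assignments, n_samples)`` binary matrix; each row is one
        case/control labelling (row 0 is conventionally the observed one).

    Returns arrays of shape ``(n_assignments,)`` for keys ``s_tau, s_comb,
    s_max, tau, s_plus, s_minus`` plus a boolean ``degenerate`` row mask.
    tau is recomputed within every assignment, as the statistic requires.
    """
    labels = np.asarray(labels)
    B = labels.shape[0]
    V = counts.shape[1]
    out_shape = (B,)
    if V == 0:
        z = np.zeros(out_shape)
        return {
            "s_tau": z, "s_comb": z.copy(), "s_max": z.copy(),
            "tau": np.full(out_shape, 0.5), "s_plus": z.copy(), "s_minus": z.copy(),
            "degenerate": np.ones(out_shape, dtype=bool),
        }
    n_case = int(labels[0].sum())
    q = n_case / labels.shape[1]
    m = counts.sum(axis=0).astype(np.int64)  # total copies per variant (fixed)
    kp = labels.astype(np.int64) @ counts.astype(np.int64)  # (B, V) copies in cases
    case_mask = 2 * kp > m[None, :]
    ctrl_mask = 2 * kp < m[None, :]

    tables = _weight_tables(m, q)
    s_plus = np.zeros(B)
    s_minus = np.zeros(B)
    for mm, (w_plus, w_minus) in tables.items():
        cols = np.flatnonzero(m == mm)
        if mm == 0:
            continue
        kp_sub = kp[:, cols]
        cm = case_mask[:, cols]
        tm = ctrl_mask[:, cols]
        wp = w_plus[kp_sub]
        wm = w_minus[kp_sub]
        s_plus += np.where(cm, wp, 0.0).sum(axis=1)
        s_minus += np.where(tm, wm, 0.0).sum(axis=1)

    n_plus = case_mask.sum(axis=1)
    n_minus = ctrl_mask.sum(axis=1)
    n_or = n_plus + n_minus
    degenerate = n_or == 0
    tau = np.where(degenerate, 0.5, n_plus / np.maximum(n_or, 1))
    return {
        "s_tau": tau * s_plus + (1.0 - tau) * s_minus,
        "s_comb": s_plus + s_minus,
        "s_max": np.maximum(s_plus, s_minus),
        "tau": tau,
        "s_plus": s_plus,
        "s_minus": s_minus,
        "degenerate": degenerate,
    }
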