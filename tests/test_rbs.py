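"""The replication-based statistic family: partition, weights, S_tau algebra,
and an independent brute-force oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rvagg import (
    Orientation,
    PhenotypeVector,
    VariantCountPair,
    compute_rbs,
    partition_variants,
    rbs_weight,
)
from rvagg.rbs import rbs_batch

from conftest import make_matrix, make_phenotype


def test_partition_counts_and_orientation():
    # 3 cases (s0-s2), 3 controls; columns: case singleton, tie, control excess
    counts = np.array(
        [
            [1, 1, 0],
            [0, 0, 0],
            [0, 0, 1],
            [0, 1, 2],
            [0, 0, 0],
            [0, 0, 1],
        ]
    )
    gm = make_matrix(counts)
    ph = make_phenotype([1, 1, 1, 0, 0, 0])
    pairs = partition_variants(gm, ph)
    assert pairs[0] == VariantCountPair(1, 0)
    assert pairs[0].orientation is Orientation.CASE_EXCESS
    assert pairs[1] == VariantCountPair(1, 1)
    assert pairs[1].orientation is Orientation.TIE
    assert pairs[2] == VariantCountPair(1, 3)
    assert pairs[2].orientation is Orientation.CONTROL_EXCESS
    # k' + k equals total copies
    for j, p in enumerate(pairs):
        assert p.k_prime + p.k == counts[:, j].sum()


def test_partition_requires_both_groups():
    gm = make_matrix(np.ones((3, 1), dtype=int))
    with pytest.raises(ValueError):
        partition_variants(gm, make_phenotype([1, 1, 1]))


@pytest.mark.parametrize(
    "k_prime, k, expected",
    [
        (1, 0, -math.log(0.5)),  # P(X >= 1), X ~ Bin(1, 1/2)
        (0, 2, -math.log(0.25)),  # P(X <= 0), X ~ Bin(2, 1/2)
    ],
)
def test_binomial_tail_weights(k_prime, k, expected):
    w = rbs_weight(VariantCountPair(k_prime, k), n_case=4, n_control=4)
    assert w == pytest.approx(expected, rel=1e-12)


def test_tie_pair_has_no_weight():
    with pytest.raises(ValueError):
        rbs_weight(VariantCountPair(1, 1), 4, 4)


def test_stau_equals_splus_when_all_case_excess():
    counts = np.zeros((6, 3), dtype=int)
    counts[0, :] = 1  # three case singletons
    gm = make_matrix(counts)
    comp = compute_rbs(gm, make_phenotype([1, 1, 1, 0, 0, 0]))
    assert comp.n_minus == 0 and comp.tau == 1.0
    assert comp.s_tau == comp.s_plus == comp.s_max == comp.s_comb


def test_stau_halves_scomb_when_balanced():
    counts = np.zeros((6, 2), dtype=int)
    counts[0, 0] = 1  # case singleton
    counts[3, 1] = 1  # control singleton
    comp = compute_rbs(make_matrix(counts), make_phenotype([1, 1, 1, 0, 0, 0]))
    assert comp.n_plus == comp.n_minus == 1
    assert comp.tau == 0.5
    assert comp.s_tau == pytest.approx(comp.s_comb / 2)


def test_stau_convex_combination_with_custom_weights():
    # 3 case-excess and 1 control-excess variants, fixed per-group weights:
    # tau = 0.75, S+ = 3 * (2/3) = 2, S- = 4 -> S_tau = .75*2 + .25*4 = 2.5
    counts = np.zeros((6, 4), dtype=int)
    counts[0, 0] = counts[0, 1] = counts[0, 2] = 1
    counts[3, 3] = 1

    def weight(pair, n_case, n_control):
        return 2.0 / 3.0 if pair.orientation is Orientation.CASE_EXCESS else 4.0

    comp = compute_rbs(make_matrix(counts), make_phenotype([1, 1, 1, 0, 0, 0]),
                       weight_fn=weight)
    assert comp.tau == 0.75
    assert (comp.s_plus, comp.s_minus) == (2.0, 4.0)
    assert comp.s_tau == pytest.approx(2.5)
    assert min(comp.s_plus, comp.s_minus) <= comp.s_tau <= max(comp.s_plus, comp.s_minus)


def test_degenerate_gene_all_ties():
    counts = np.array([[1], [0], [0], [1], [0], [0]])
    comp = compute_rbs(make_matrix(counts), make_phenotype([1, 1, 1, 0, 0, 0]))
    assert comp.degenerate
    assert comp.tau == 0.5
    assert comp.s_tau == comp.s_comb == comp.s_max == 0.0


# ---------------------------------------------------------------------------
# Independent brute-force oracle: recount copies sample by sample and
# re-evaluate the binomial tails from the pmf definition with math.comb.
# ---------------------------------------------------------------------------

def brute_force_rbs(counts, status):
    n_case = sum(status)
    n = len(status)
    q = n_case / n
    s_plus = s_minus = 0.0
    n_plus = n_minus = 0
    for j in range(counts.shape[1]):
        kp = sum(c for c, y in zip(counts[:, j], status) if y == 1)
        k = sum(c for c, y in zip(counts[:, j], status) if y == 0)
        m = kp + k

        def pmf(x):
            return math.comb(m, x) * q**x * (1 - q) ** (m - x)

        if kp > k:
            n_plus += 1
            s_plus += -math.log(sum(pmf(x) for x in range(kp, m + 1)))
        elif kp < k:
            n_minus += 1
            s_minus += -math.log(sum(pmf(x) for x in range(0, kp + 1)))
    if n_plus + n_minus == 0:
        return dict(tau=0.5, s_plus=0.0, s_minus=0.0, s_max=0.0, s_comb=0.0, s_tau=0.0)
    tau = n_plus / (n_plus + n_minus)
    return dict(
        tau=tau, s_plus=s_plus, s_minus=s_minus,
        s_max=max(s_plus, s_minus), s_comb=s_plus + s_minus,
        s_tau=tau * s_plus + (1 - tau) * s_minus,
    )


@pytest.mark.parametrize("seed", range(10))
def test_brute_force_oracle_small_genes(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    v = int(rng.integers(1, 6))
    counts = rng.integers(0, 3, size=(n, v))
    n_case = int(rng.integers(1, n))
    status = np.zeros(n, dtype=int)
    status[rng.choice(n, n_case, replace=False)] = 1
    gm = make_matrix(counts)
    comp = compute_rbs(gm, make_phenotype(status))
    expected = brute_force_rbs(gm.counts, status)  # oracle sees oriented counts
    for key, val in expected.items():
        assert getattr(comp, key) == pytest.approx(val, rel=1e-10), key


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------

small_genes = st.tuples(
    st.integers(4, 10),  # samples
    st.integers(1, 6),  # variants
    st.integers(0, 2**31 - 1),
)


def _random_gene(n, v, seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 3, size=(n, v))
    n_case = int(rng.integers(1, n))
    status = np.zeros(n, dtype=int)
    status[rng.choice(n, n_case, replace=False)] = 1
    return counts, status


@given(small_genes)
@settings(deadline=None, max_examples=60)
def test_tau_in_unit_interval_and_convexity(params):
    counts, status = _random_gene(*params)
    comp = compute_rbs(make_matrix(counts), make_phenotype(status))
    assert 0.0 <= comp.tau <= 1.0
    assert min(comp.s_plus, comp.s_minus) - 1e-12 <= comp.s_tau
    assert comp.s_tau <= max(comp.s_plus, comp.s_minus) + 1e-12


@given(small_genes)
@settings(deadline=None, max_examples=40)
def test_label_swap_symmetry(params):
    counts, status = _random_gene(*params)
    if status.sum() in (0, len(status)):
        return
    a = compute_rbs(make_matrix(counts), make_phenotype(status))
    b = compute_rbs(make_matrix(counts), make_phenotype(1 - status))
    assert b.s_plus == pytest.approx(a.s_minus)
    assert b.s_minus == pytest.approx(a.s_plus)
    assert b.tau == pytest.approx(1 - a.tau)
    assert b.s_comb == pytest.approx(a.s_comb)
    assert b.s_max == pytest.approx(a.s_max)
    assert b.s_tau == pytest.approx(b.tau * a.s_minus + (1 - b.tau) * a.s_plus)


@given(small_genes)
@settings(deadline=None, max_examples=40)
def test_order_invariance_and_tie_padding(params):
    counts, status = _random_gene(*params)
    gm = make_matrix(counts)
    ph = make_phenotype(status)
    base = compute_rbs(gm, ph)

    rng = np.random.default_rng(0)
    vperm = rng.permutation(counts.shape[1])
    sperm = rng.permutation(counts.shape[0])
    shuffled = make_matrix(
        counts[np.ix_(sperm, vperm)],
        sample_ids=[f"s{i}" for i in sperm],
        variant_ids=[f"v{j}" for j in vperm],
    )
    again = compute_rbs(shuffled, ph)  # aligned by sample id
    assert again.s_tau == pytest.approx(base.s_tau)
    assert again.tau == pytest.approx(base.tau)

    # appending a tie variant (1 copy in a case, 1 in a control) changes nothing
    tie = np.zeros((len(status), 1), dtype=int)
    tie[np.argmax(status == 1), 0] = 1
    tie[np.argmax(status == 0), 0] = 1
    padded = compute_rbs(make_matrix(np.hstack([counts, tie])), ph)
    for f in ("s_plus", "s_minus", "tau", "s_max", "s_comb", "s_tau"):
        assert getattr(padded, f) == pytest.approx(getattr(base, f))


def test_batch_matches_scalar_over_label_stack(rng):
    counts = rng.integers(0, 3, size=(12, 5))
    gm = make_matrix(counts)
    labels = np.array([rng.permutation([1] * 5 + [0] * 7) for _ in range(50)])
    batch = rbs_batch(gm.counts, labels)
    for b in range(50):
        comp = compute_rbs(gm, PhenotypeVector(gm.sample_ids, labels[b]))
        assert batch["s_tau"][b] == pytest.approx(comp.s_tau)
        assert batch["s_comb"][b] == pytest.approx(comp.s_comb)
        assert batch["s_max"][b] == pytest.approx(comp.s_max)
        assert batch["degenerate"][b] == comp.degenerate
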