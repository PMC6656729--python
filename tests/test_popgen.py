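"""Weir-Cockerham haploid F_ST, LD pruning, permutation test, kinship."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slowfast.popgen import (
    fst_permutation_null,
    kinship_matrix,
    ld_prune,
    multilocus_fst,
    neutral_fst,
    snp_fst,
)
from tests.conftest import counts_to_genotypes, labels_from_sizes, make_genotypes


def wc84_haploid_oracle(alt_counts, sizes):
    """Independent explicit-formula evaluation of the WC84 haploid components.

    Deliberately written as plain scalar arithmetic over a count table,
    not sharing any code with the implementation under test.
    """
    r = len(sizes)
    N = sum(sizes)
    ps = [a / n for a, n in zip(alt_counts, sizes)]
    p_bar = sum(a for a in alt_counts) / N
    msp = sum(n * (p - p_bar) ** 2 for n, p in zip(sizes, ps)) / (r - 1)
    msg = sum(n * p * (1 - p) for n, p in zip(sizes, ps)) / (N - r)
    n_c = (N - sum(n * n for n in sizes) / N) / (r - 1)
    a = (msp - msg) / n_c
    b = msg
    if a + b == 0:
        return np.nan
    return a / (a + b)


def theta_of_counts(alt_counts, sizes):
    g = counts_to_genotypes(alt_counts, sizes)
    labels = labels_from_sizes(sizes)
    return snp_fst(g, labels).iloc[0]


def test_fixed_difference_gives_theta_one():
    assert theta_of_counts([0, 20], [20, 20]) == pytest.approx(1.0)


def test_identical_allele_counts_give_nonpositive_theta():
    assert theta_of_counts([5, 5], [20, 20]) <= 0.0


def test_hand_evaluated_two_population_table():
    # 2 pops of 10, alt counts 1 and 9: a = (3.2 - 0.1)/10, b = 0.1
    expected = 0.31 / 0.41
    assert theta_of_counts([1, 9], [10, 10]) == pytest.approx(expected, abs=1e-12)
    assert wc84_haploid_oracle([1, 9], [10, 10]) == pytest.approx(expected, abs=1e-12)


def test_monomorphic_snp_is_undefined_not_zero():
    assert np.isnan(theta_of_counts([0, 0], [10, 10]))
    assert np.isnan(theta_of_counts([10, 10], [10, 10]))


def test_oracle_equivalence_on_random_count_tables(rng):
    """Per-SNP theta-hat matches the independent formula on random tables."""
    checked = 0
    while checked < 100:
        r = int(rng.integers(2, 5))
        sizes = [int(rng.integers(2, 7)) for _ in range(r)]
        counts = [int(rng.integers(0, n + 1)) for n in sizes]
        expected = wc84_haploid_oracle(counts, sizes)
        got = theta_of_counts(counts, sizes)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-12)
        checked += 1


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.tuples(st.integers(2, 6), st.integers(0, 6)), min_size=2, max_size=4))
def test_theta_invariant_to_allele_relabelling(table):
    sizes = [n for n, _ in table]
    counts = [min(c, n) for n, c in table]
    flipped = [n - c for n, c in zip(sizes, counts)]
    t1 = theta_of_counts(counts, sizes)
    t2 = theta_of_counts(flipped, sizes)
    if np.isnan(t1):
        assert np.isnan(t2)
    else:
        assert t1 == pytest.approx(t2, abs=1e-12)


def test_multilocus_single_snp_identity_and_all_fixed():
    g = counts_to_genotypes([1, 9], [10, 10])
    labels = labels_from_sizes([10, 10])
    ml = multilocus_fst(g, labels)
    assert ml["theta_ratio_of_sums"] == pytest.approx(0.31 / 0.41, abs=1e-12)
    assert ml["theta_mean_per_snp"] == pytest.approx(0.31 / 0.41, abs=1e-12)

    fixed = np.column_stack([np.r_[np.zeros(10), np.ones(10)]] * 4)
    gf = make_genotypes(fixed)
    mlf = multilocus_fst(gf, labels)
    assert mlf["theta_ratio_of_sums"] == pytest.approx(1.0)
    assert mlf["pairwise"].loc["group_1", "group_2"] == pytest.approx(1.0)


def test_ld_prune_drops_duplicate_within_window(rng):
    col = rng.integers(0, 2, 50).astype(float)
    other = rng.integers(0, 2, 50).astype(float)
    g = make_genotypes(
        np.column_stack([col, col, other]), positions=[1000, 2000, 3000]
    )
    kept = ld_prune(g)
    assert 0 in kept and 1 not in kept and 2 in kept


def test_ld_prune_keeps_identical_snps_outside_window(rng):
    col = rng.integers(0, 2, 50).astype(float)
    g = make_genotypes(np.column_stack([col, col]), positions=[1000, 60_000])
    assert ld_prune(g, window_kb=50).tolist() == [0, 1]


def test_ld_prune_zero_variance_snp_kept(rng):
    g = make_genotypes(
        np.column_stack([np.zeros(20), rng.integers(0, 2, 20).astype(float)]),
        positions=[100, 200],
    )
    assert ld_prune(g).tolist() == [0, 1]


def test_ld_prune_output_has_no_high_r2_pair_within_window():
    from slowfast.synthetic import SimGenoParams, simulate_genotypes

    g, _ = simulate_genotypes(
        SimGenoParams(
            n_pops=2, pop_sizes=(50, 50), n_snps=400, frac_admixed=0.0,
            ld_block_size=4, ld_flip_prob=0.02, n_chroms=1, seed=5,
        )
    )
    kept = ld_prune(g, r2_max=0.1, window_kb=50, step_snps=50)
    assert kept.size < g.n_snps  # the block structure forces drops
    pos = g.snps["pos"].to_numpy()[kept]
    d = g.dosage[:, kept]
    for i in range(kept.size - 1):
        for j in range(i + 1, kept.size):
            if pos[j] - pos[i] > 50_000:
                break
            if d[:, i].std() == 0 or d[:, j].std() == 0:
                continue
            assert np.corrcoef(d[:, i], d[:, j])[0, 1] ** 2 < 0.1 + 1e-12


def test_ld_prune_mostly_retains_independent_snps(rng):
    d = (rng.random((300, 500)) < 0.4).astype(float)
    g = make_genotypes(d, positions=np.arange(1, 501) * 100)
    kept = ld_prune(g)
    assert kept.size >= 0.99 * 500


def test_permutation_determinism_and_fixed_difference_significance(rng):
    d = np.column_stack(
        [np.r_[np.zeros(10), np.ones(10)], rng.integers(0, 2, 20).astype(float)]
    )
    g = make_genotypes(d)
    labels = labels_from_sizes([10, 10])
    r1 = fst_permutation_null(g, labels, n_perm=200, seed=7)
    r2 = fst_permutation_null(g, labels, n_perm=200, seed=7)
    pd.testing.assert_frame_equal(r1, r2)
    assert bool(r1.loc["snp0", "significant"])  # theta = 1 beats any permutation


def test_neutral_fst_median_rules():
    per_snp = pd.DataFrame(
        {
            "theta": [0.05, 0.10, 0.20, 0.9, 0.9],
            "null_q": 0.0,
            "significant": [True, True, True, False, True],
        },
        index=pd.Index([f"snp{i}" for i in range(5)], name="id"),
    )
    snps = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": range(1, 6),
            "id": [f"snp{i}" for i in range(5)],
            "intergenic": [True, True, True, True, False],
        }
    )
    assert neutral_fst(per_snp, snps) == pytest.approx(0.10)
    one = per_snp.copy()
    one["significant"] = [False, True, False, False, False]
    assert neutral_fst(one, snps) == pytest.approx(0.10)
    none = per_snp.copy()
    none["significant"] = False
    with pytest.raises(ValueError, match="intergenic"):
        neutral_fst(none, snps)


def test_kinship_identical_rows_and_diagonal(rng):
    row = rng.integers(0, 2, 200).astype(float)
    d = np.vstack([row, row, rng.integers(0, 2, 200).astype(float)])
    g = make_genotypes(d, positions=np.arange(1, 201) * 100)
    K = kinship_matrix(g)
    assert K.iloc[0, 1] == pytest.approx(K.iloc[0, 0], abs=1e-12)
    assert K.iloc[0, 1] == pytest.approx(K.iloc[1, 1], abs=1e-12)
    assert np.diag(K).mean() == pytest.approx(1.0, abs=0.05)


def test_kinship_null_offdiagonals_small(rng):
    d = (rng.random((20, 1000)) < 0.5).astype(float)
    g = make_genotypes(d, positions=np.arange(1, 1001) * 100)
    K = kinship_matrix(g).to_numpy()
    off = K[~np.eye(20, dtype=bool)]
    assert np.abs(off).max() < 0.15
    # column centering makes the off-diagonal mean exactly -mean(diag)/(n-1)
    assert off.mean() == pytest.approx(-np.diag(K).mean() / 19, abs=1e-12)
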