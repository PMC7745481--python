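import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coevdimer.asa import ASAProfile, all_columns_ermsa, extract_ermsa
from coevdimer.covariation import (
    CovariationError,
    CovariationMatrix,
    clr_transform,
    extract_inter_block,
    mi_matrices,
    mi_matrix,
    mip_transform,
    read_ccmpred_matrix,
    write_matrix_tsv,
)
from coevdimer.msa import AlignedFamily, PairedMSA
from conftest import random_pair
from oracles import brute_clr, brute_mi_matrices, brute_mip, columns_of

LOG21_2 = math.log(2, 21)


def family_from_columns(cols: list[str], family_id="f") -> AlignedFamily:
    n = len(cols[0])
    rows = ["".join(col[i] for col in cols) for i in range(n)]
    species = [f"sp{k:03d}" for k in range(n)]
    return AlignedFamily(family_id, rows, species, query_index=0)


def pair_from_columns(cols_a, cols_b, dimer_id="d") -> PairedMSA:
    return PairedMSA(
        dimer_id,
        family_from_columns(cols_a, "a"),
        family_from_columns(cols_b, "b"),
    )


def matrix(values, method="nMI") -> CovariationMatrix:
    values = np.asarray(values, dtype=float)
    return CovariationMatrix(
        "d", method, 0.0, values,
        np.arange(values.shape[0]), np.arange(values.shape[1]),
    )


# --- closed-form spot checks ----------------------------------------------


def test_fully_conserved_columns_have_zero_mi():
    """H(x) = H(y) = H(x,y) = 0, so MI = 0 and nMI = 0 by the 0/0 rule."""
    p = pair_from_columns(["A" * 10], ["C" * 10])
    e = all_columns_ermsa(p)
    mi, nmi = mi_matrices(e)
    assert mi.scores[0, 0] == 0.0
    assert nmi.scores[0, 0] == 0.0


def test_two_state_deterministic_coupling():
    """Perfectly co-varying two-state columns: MI = log21(2), nMI = 1."""
    x = "AAAAACCCCC"
    y = "DDDDDEEEEE"
    e = all_columns_ermsa(pair_from_columns([x], [y]))
    mi, nmi = mi_matrices(e)
    assert mi.scores[0, 0] == pytest.approx(LOG21_2, abs=1e-14)
    assert nmi.scores[0, 0] == pytest.approx(1.0, abs=1e-14)


def test_gap_heavy_column_scores_zero():
    """A column with >= 80% gaps zeroes every pair it belongs to."""
    gappy = "AA--------"  # 8/10 gaps
    informative = "AAAAACCCCC"
    partner = "DDDDDEEEEE"
    e = all_columns_ermsa(pair_from_columns([gappy, informative], [partner]))
    mi, nmi = mi_matrices(e)
    assert mi.scores[0, 0] == 0.0
    assert nmi.scores[0, 0] == 0.0
    assert mi.scores[1, 0] > 0.0  # the clean column still scores


def test_uniform_matrix_mip_is_zero():
    out = mip_transform(matrix(np.full((3, 4), 0.7), method="MI"))
    np.testing.assert_allclose(out.scores, 0.0, atol=1e-15)


def test_zero_matrix_mip_is_zero():
    out = mip_transform(matrix(np.zeros((2, 3)), method="MI"))
    np.testing.assert_array_equal(out.scores, 0.0)


def test_constant_matrix_clr_is_zero():
    out = clr_transform(matrix(np.full((4, 5), 0.3)))
    np.testing.assert_array_equal(out.scores, 0.0)


def test_mip_worked_example():
    """APC(1,1) = (0.2 x 0.15) / 0.25 = 0.12, so MIp(1,1) = -0.02."""
    out = mip_transform(matrix([[0.1, 0.3], [0.2, 0.4]], method="MI"))
    assert out.scores[0, 0] == pytest.approx(-0.02, abs=1e-12)
    np.testing.assert_allclose(
        out.scores, brute_mip([[0.1, 0.3], [0.2, 0.4]]), atol=1e-12
    )


def test_clr_worked_example_against_oracle():
    vals = [[0.2, 0.4], [0.1, 0.3]]
    out = clr_transform(matrix(vals))
    np.testing.assert_allclose(out.scores, brute_clr(vals), atol=1e-12)


def test_clr_entry_below_both_means_is_zero():
    vals = np.array([[0.9, 0.8], [0.7, 0.1]])
    out = clr_transform(matrix(vals))
    assert out.scores[1, 1] == 0.0  # below its row and column mean
    assert np.all(out.scores >= 0.0)


# --- brute-force oracle equivalence ---------------------------------------


@settings(max_examples=30, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_mi_pipeline_matches_brute_force(seed):
    """MI, nMI, MIp and CLR agree with direct dictionary-counting
    implementations on random small dimers, including the gap rule."""
    rng = np.random.default_rng(seed)
    n_seq = int(rng.integers(5, 31))
    p = random_pair(rng, n_seq, int(rng.integers(2, 9)), int(rng.integers(2, 9)),
                    gap_rate=0.2)
    # occasionally force a gap-heavy column (query row must stay gap-free)
    if rng.random() < 0.5 and n_seq >= 5:
        seqs = p.family_a.sequences
        n_gaps = int(math.ceil(0.8 * n_seq)) - 1
        new = []
        for k, s in enumerate(seqs):
            c = "-" if 1 <= k <= n_gaps else s[0]
            new.append(c + s[1:])
        object.__setattr__(p.family_a, "sequences", new)

    e = all_columns_ermsa(p)
    mi, nmi = mi_matrices(e)
    ref_mi, ref_nmi = brute_mi_matrices(
        columns_of(p.family_a.sequences), columns_of(p.family_b.sequences)
    )
    np.testing.assert_allclose(mi.scores, ref_mi, atol=1e-12)
    np.testing.assert_allclose(nmi.scores, ref_nmi, atol=1e-12)
    np.testing.assert_allclose(
        mip_transform(nmi).scores, brute_mip(nmi.scores.tolist()), atol=1e-12
    )
    np.testing.assert_allclose(
        clr_transform(nmi).scores, brute_clr(nmi.scores.tolist()), atol=1e-12
    )


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_mi_symmetry_under_family_swap(seed):
    """mi_matrix(A, B) equals the transpose of mi_matrix(B, A)."""
    rng = np.random.default_rng(seed)
    p = random_pair(rng, 12, 5, 7, gap_rate=0.15)
    swapped = PairedMSA(p.dimer_id, p.family_b, p.family_a)
    mi_ab = mi_matrix(all_columns_ermsa(p))
    mi_ba = mi_matrix(all_columns_ermsa(swapped))
    np.testing.assert_allclose(mi_ab.scores, mi_ba.scores.T, atol=1e-12)


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_normalized_mi_bounded(seed):
    rng = np.random.default_rng(seed)
    p = random_pair(rng, 15, 6, 6, gap_rate=0.1)
    nmi = mi_matrix(all_columns_ermsa(p), normalized=True)
    assert np.all(nmi.scores >= 0.0)
    assert np.all(nmi.scores <= 1.0 + 1e-12)


def test_mip_row_sums_vanish_for_rank_one_input():
    """For a rank-one (outer-product) matrix the APC reproduces the
    matrix exactly, so MIp is identically zero."""
    r = np.array([0.1, 0.4, 0.2])
    c = np.array([0.3, 0.5])
    out = mip_transform(matrix(np.outer(r, c), method="MI"))
    np.testing.assert_allclose(out.scores, 0.0, atol=1e-14)


def test_mip_accepts_raw_or_normalized_only():
    with pytest.raises(CovariationError):
        mip_transform(matrix(np.ones((2, 2)), method="CLR"))
    with pytest.raises(CovariationError):
        clr_transform(matrix(np.ones((2, 2)), method="MI"))


# --- threshold slicing consistency ----------------------------------------


def test_sliced_full_matrix_equals_ermsa_matrix(rng):
    """Computing MI on the full dimer and slicing to the exposed columns
    gives the same matrix as computing on the extracted ER-MSA: per-pair
    scores do not depend on which other columns are retained."""
    p = random_pair(rng, 20, 10, 8, gap_rate=0.15)
    asa_a = ASAProfile("a", rng.random(10))
    asa_b = ASAProfile("b", rng.random(8))
    t = 0.35
    e = extract_ermsa(p, asa_a, asa_b, t)
    direct_mi, direct_nmi = mi_matrices(e)
    full_mi, full_nmi = mi_matrices(all_columns_ermsa(p))
    ia, ib = e.column_map_a, e.column_map_b
    np.testing.assert_allclose(
        direct_mi.scores, full_mi.scores[np.ix_(ia, ib)], atol=1e-12
    )
    np.testing.assert_allclose(
        direct_nmi.scores, full_nmi.scores[np.ix_(ia, ib)], atol=1e-12
    )


# --- CCMpred adapter -------------------------------------------------------


def test_extract_inter_block_indexing():
    raw = np.arange(25, dtype=float).reshape(5, 5)
    raw = (raw + raw.T) / 2  # make symmetric
    block = extract_inter_block(raw, 2, 3)
    np.testing.assert_array_equal(block.scores, raw[:2, 2:])
    np.testing.assert_array_equal(block.scores, raw[2:, :2].T)


def test_extract_inter_block_averages_asymmetric_input():
    rng = np.random.default_rng(0)
    raw = rng.random((5, 5))
    block = extract_inter_block(raw, 2, 3)
    np.testing.assert_allclose(
        block.scores, 0.5 * (raw[:2, 2:] + raw[2:, :2].T), atol=1e-15
    )


def test_extract_inter_block_dimension_mismatch():
    with pytest.raises(CovariationError, match="expected"):
        extract_inter_block(np.zeros((6, 6)), 2, 3)


def test_ccmpred_matrix_io(tmp_path):
    raw = np.array([[0.0, 1.5, 0.25], [1.5, 0.0, 2.0], [0.25, 2.0, 0.0]])
    path = tmp_path / "raw.mat"
    np.savetxt(path, raw)
    back = read_ccmpred_matrix(path)
    np.testing.assert_allclose(back, raw)
    path.write_text("0 1\n2 3\n4 5\n")
    with pytest.raises(CovariationError, match="square"):
        read_ccmpred_matrix(path)


def test_matrix_tsv_written_with_query_coordinates(tmp_path, rng):
    p = random_pair(rng, 8, 4, 3)
    mi = mi_matrix(all_columns_ermsa(p))
    out = tmp_path / "m.tsv"
    write_matrix_tsv(mi, out)
    lines = out.read_text().splitlines()
    assert lines[1].split("\t") == ["pos", "1", "2", "3"]
    assert len(lines) == 2 + 4
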