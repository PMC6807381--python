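"""alignment: brute-force optimality, percentage conventions, MSA, conservation."""

from __future__ import annotations

import itertools
import random

import numpy as np
import pytest

from isfamily.alignment import (MSA, AlignParams, AlignmentError, conservation,
                                global_align, identity_matrix, percent_identity,
                                percent_similarity, progressive_msa)

PROT = AlignParams.protein()
NT = AlignParams.nucleotide()
AA = "ACDEFGHIKLMNPQRSTVWY"


# --- independent enumeration oracle ---------------------------------------

def enumerate_scores(a: str, b: str, params: AlignParams):
    """Score of every global alignment, gap runs charged open + ext*(L-1)."""
    alpha, S = params.alphabet_and_scores()
    idx = {c: i for i, c in enumerate(alpha)}

    def rec(i, j, last_gap):
        if i == len(a) and j == len(b):
            yield 0.0
            return
        if i < len(a) and j < len(b):
            s = S[idx[a[i]], idx[b[j]]]
            for rest in rec(i + 1, j + 1, None):
                yield s + rest
        if i < len(a):
            cost = params.gap_extend if last_gap == "U" else params.gap_open
            for rest in rec(i + 1, j, "U"):
                yield rest - cost
        if j < len(b):
            cost = params.gap_extend if last_gap == "L" else params.gap_open
            for rest in rec(i, j + 1, "L"):
                yield rest - cost

    return rec(0, 0, None)


@pytest.mark.parametrize("seed,params,alpha", [(0, NT, "ACGT"), (1, PROT, AA)])
def test_score_equals_bruteforce_optimum(seed, params, alpha):
    rng = random.Random(seed)
    for _ in range(150):
        a = "".join(rng.choice(alpha) for _ in range(rng.randint(1, 5)))
        b = "".join(rng.choice(alpha) for _ in range(rng.randint(1, 5)))
        got = global_align(a, b, params).score
        want = max(enumerate_scores(a, b, params))
        assert got == pytest.approx(want, abs=1e-6), (a, b)


def test_score_symmetric_and_identity_order_invariant():
    rng = random.Random(7)
    for _ in range(40):
        a = "".join(rng.choice(AA) for _ in range(rng.randint(5, 30)))
        b = "".join(rng.choice(AA) for _ in range(rng.randint(5, 30)))
        ab, ba = global_align(a, b, PROT), global_align(b, a, PROT)
        assert ab.score == pytest.approx(ba.score, abs=1e-6)
        if not np.isnan(ab.identity_pct):
            assert ab.identity_pct == pytest.approx(ba.identity_pct, abs=1e-9)


def test_score_matches_biopython_pairwise_aligner():
    """Independent cross-check on realistic lengths with the same gap model."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.1
    rng = random.Random(3)
    for _ in range(10):
        a = "".join(rng.choice(AA) for _ in range(rng.randint(30, 60)))
        b = "".join(rng.choice(AA) for _ in range(rng.randint(30, 60)))
        assert global_align(a, b, PROT).score == pytest.approx(aligner.score(a, b),
                                                               abs=1e-6)


def test_identical_sequences_align_without_gaps():
    pair = global_align("MKLVDDE", "MKLVDDE", PROT)
    assert pair.aligned_a == pair.aligned_b == "MKLVDDE"
    _, S = PROT.alphabet_and_scores()
    alpha, _ = PROT.alphabet_and_scores()
    assert pair.identity_pct == 100.0 and pair.similarity_pct == 100.0


def test_nucleotide_identity_single_mismatch():
    assert global_align("AAAA", "AAAT", NT).identity_pct == 75.0


def test_identity_excludes_terminal_overhangs_counts_internal_gaps():
    # overhang: the short sequence sits inside the long one at 100 % identity
    assert global_align("ACGTACGT", "GTACG", NT).identity_pct == 100.0
    # internal deletion: gap column stays in the denominator
    a = "ACGTACGTACGTACGTACGT"
    b = a[:10] + a[12:]
    pair = global_align(a, b, NT)
    assert len(pair) == 20
    assert pair.identity_pct == pytest.approx(100.0 * 18 / 20)


def test_identity_magnitude_mirrors_published_rounding():
    # a pair differing at 4 of 790 aligned positions reads 99.49 % at 1 dp
    rng = random.Random(9)
    a = "".join(rng.choice("ACGT") for _ in range(790))
    b = list(a)
    for pos in (100, 300, 500, 700):
        b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
    pair = global_align(a, "".join(b), NT)
    assert round(pair.identity_pct, 2) == 99.49


def test_similarity_counts_positive_scoring_pairs():
    # D vs E scores +2 in BLOSUM62 (similar), D vs P scores -1 (not)
    pair = global_align("MDDD", "MEEE", PROT)
    assert pair.identity_pct == 25.0
    assert pair.similarity_pct == 100.0
    pair2 = global_align("MDDD", "MPPP", PROT)
    assert pair2.similarity_pct == 25.0


def test_empty_and_gapped_inputs_rejected():
    with pytest.raises(AlignmentError):
        global_align("", "ACGT", NT)
    with pytest.raises(AlignmentError):
        global_align("AC-GT", "ACGT", NT)


def test_identity_matrix_consistency(small_records):
    sub = small_records.subset(small_records.names[:5])
    idm = identity_matrix(sub, "nt")
    vals = idm.values
    assert np.allclose(vals, vals.T)
    assert np.allclose(np.diag(vals), 100.0)
    a, b = sub.names[0], sub.names[3]
    direct = global_align(sub[a].sequence, sub[b].sequence, idm.params)
    assert vals.loc[a, b] == pytest.approx(direct.identity_pct)


def test_identity_matrix_two_identical_records():
    idm = identity_matrix([("x", "ACGT" * 40), ("y", "ACGT" * 40)], "nt")
    assert np.allclose(idm.values.to_numpy(), 100.0)


def test_identity_matrix_rejects_duplicates():
    with pytest.raises(AlignmentError, match="duplicate"):
        identity_matrix([("x", "ACGT" * 30), ("x", "ACGT" * 30)], "nt")


def test_identity_close_pairs_match_generator_bookkeeping(small_family):
    """For closely related pairs (the ones isoform calling depends on) the
    aligned identity reproduces the simulator's recorded substitution
    fraction to 0.5 %.  At high divergence the optimal affine alignment may
    legitimately trade mismatches for gaps, so distant pairs are not held to
    the Hamming bookkeeping."""
    records, truth = small_family
    div = truth.pairwise_nt_divergence
    names = records.names
    checked = 0
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if div.loc[a, b] > 0.12:
                continue
            pair = global_align(records[a].sequence, records[b].sequence, NT)
            want = 100.0 * (1.0 - div.loc[a, b])
            assert pair.identity_pct == pytest.approx(want, abs=0.5), (a, b)
            checked += 1
    assert checked >= 2  # the injected isoform pairs at least


def test_progressive_msa_identical_sequences_gap_free():
    msa = progressive_msa([("a", "MKLV" * 10), ("b", "MKLV" * 10),
                           ("c", "MKLV" * 10)], level="aa")
    assert msa.n_columns == 40
    assert all("-" not in r for r in msa.rows)


def test_progressive_msa_two_sequences_reduces_to_pairwise():
    a, b = "MKLVWDE", "MKLVDE"
    msa = progressive_msa([("a", a), ("b", b)], level="aa")
    pair = global_align(a, b, PROT)
    assert msa.rows == [pair.aligned_a, pair.aligned_b]


def test_progressive_msa_no_indel_family_is_stacking(tiny_family):
    records, _ = tiny_family
    msa = progressive_msa(records, level="aa")
    assert all("-" not in r for r in msa.rows)
    assert msa.rows == [r.tnp for r in records]
    assert msa.names == records.names


def test_progressive_msa_rows_degap_to_inputs(small_records):
    sub = small_records.subset(small_records.names[:6])
    msa = progressive_msa(sub, level="aa")
    for rec in sub:
        assert msa.degapped(rec.name) == rec.tnp


def test_conservation_classes_and_flags():
    # column 1: D in all 65 rows; column 2: H in 62 of 65;
    # column 3: 45 of 65 identical (P) with dissimilar G elsewhere
    rows = []
    for i in range(65):
        c1 = "D"
        c2 = "H" if i < 62 else "P"
        c3 = "P" if i < 45 else "G"
        rows.append(c1 + c2 + c3)
    msa = MSA([f"r{i}" for i in range(65)], rows)
    prof = conservation(msa, k=3)
    assert prof.classes[0] == "100"
    assert prof.flags(0)[0] and prof.flags(3)[0]
    assert prof.flags(3)[1] is True and prof.flags(2)[1] is False
    assert prof.classes[2] == "60-79"
    # flags are monotone in k
    for col in range(3):
        flags = [prof.flags(k)[col] for k in range(5)]
        assert flags == sorted(flags)
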