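"""Folding backends, the enumeration oracle, and hairpin geometry."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from sporomir import structure as st
from sporomir.seqio import revcomp


def _random_rna(rng, n):
    return "".join(rng.choice("ACGU") for _ in range(n))


# ------------------------------------------------------------------- folding

@pytest.mark.parametrize("backend", ["vienna", "stacking"])
def test_unpairable_sequence_folds_open(backend):
    fr = st.fold("A" * 20, backend)
    assert fr.energy == 0.0
    assert set(fr.dotbracket) == {"."}
    assert all(p == -1 for p in fr.partner)


@pytest.mark.parametrize("backend", ["vienna", "stacking"])
def test_designed_gc_stem_is_stable_single_hairpin(backend):
    stem = "GCCGGCGCCGGCGGCCGCGGCCGC"            # 24 bp once paired
    seq = stem + "AAACAA" + revcomp(stem).replace("T", "U")
    fr = st.fold(seq, backend)
    assert fr.energy < -18.0
    dec = st.decompose_hairpin(fr)
    assert dec.is_single_stem


def test_fold_refuses_short_and_bad_sequences():
    with pytest.raises(st.FoldError):
        st.fold("ACGUACGUACG")                   # < 15 nt
    with pytest.raises(st.FoldError):
        st.fold("ACGUACGUACGUACGNN")


def test_dp_energy_matches_enumeration_oracle():
    """Stacking-model MFE equals the brute-force minimum over every
    non-crossing structure, and its structure rescans to its energy."""
    rng = random.Random(7)
    for _ in range(20):
        seq = _random_rna(rng, rng.randint(15, 26))
        dp = st.fold(seq, "stacking")
        bf_e, _ = st.brute_force_mfe(seq)
        assert abs(dp.energy - bf_e) < 1e-6, seq
        if dp.energy < 0:
            assert abs(st.structure_energy(seq, dp.partner) - dp.energy) < 1e-6
        assert abs(st.oracle_min_energy(seq) - bf_e) < 1e-6


def test_extending_perfect_stem_never_raises_mfe():
    rng = random.Random(3)
    for _ in range(5):
        n = rng.randint(6, 10)
        stem = "".join(rng.choice("GC") for _ in range(n))
        seq_small = stem + "AAAA" + revcomp(stem).replace("T", "U")
        bigger = "G" + stem + "AAAA" + revcomp(stem).replace("T", "U") + "C"
        e1 = st.fold(seq_small, "stacking").energy
        e2 = st.fold(bigger, "stacking").energy
        assert e2 <= e1 + 1e-9


@pytest.mark.parametrize("backend", ["vienna", "stacking"])
def test_backend_contract_on_random_sequences(backend):
    """Any backend: balanced non-crossing brackets, legal pairs only,
    energy <= 0, and every fold decomposes without exception."""
    rng = random.Random(11)
    for _ in range(15):
        seq = _random_rna(rng, rng.randint(15, 60))
        fr = st.fold(seq, backend)
        assert fr.energy <= 0.0
        pairs = st.dotbracket_to_pairs(fr.dotbracket)   # raises if unbalanced
        assert pairs == fr.partner
        for i, j in enumerate(fr.partner):
            if j > i:
                assert st.can_pair(seq[i], seq[j])
                assert j - i - 1 >= st.MIN_LOOP
        st.decompose_hairpin(fr)                        # total


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st_h.text(alphabet="ACGU", min_size=10, max_size=16))
def test_enumerated_structures_are_valid(seq):
    for partner in st.enumerate_structures(seq, limit=200):
        for i, j in enumerate(partner):
            if j > i:
                assert st.can_pair(seq[i], seq[j])
                assert j - i - 1 >= st.MIN_LOOP
        e = st.structure_energy(seq, partner)
        assert e == e                                   # finite


def test_structure_energy_rejects_illegal_pair():
    with pytest.raises(ValueError):
        st.structure_energy("AAAAGAAA", (7, -1, -1, -1, -1, -1, -1, 0))


def test_structure_sampler_is_uniformly_valid():
    import numpy as np
    rng = np.random.default_rng(0)
    seq = "GCAUCGAUGGCAUGCAUCGGAUCC"
    total = st.count_structures(seq)
    assert total > 1
    seen = set()
    for partner in st.sample_structures(seq, 50, rng):
        seen.add(partner)
        st.structure_energy(seq, partner)               # validity
    assert len(seen) > 5


# ------------------------------------------------------------- decomposition

def _fold_from_db(seq, db):
    return st.FoldResult(seq, db, -1.0, st.dotbracket_to_pairs(db))


def test_two_stems_are_not_a_single_hairpin():
    seq = "GGGGAAAACCCCAAGGGGAAAACCCC"
    db_ = "((((....))))..((((....))))"
    dec = st.decompose_hairpin(_fold_from_db(seq, db_))
    assert not dec.is_single_stem


def test_perfect_hairpin_decomposition_symmetry():
    seq = "GGGGGAAAACCCCC"
    db_ = "(((((....)))))"
    dec = st.decompose_hairpin(_fold_from_db(seq, db_))
    assert dec.is_single_stem
    assert dec.arm5 == (0, 4) and dec.arm3 == (9, 13)
    assert dec.loop == (5, 8)


def test_bulged_hairpin_keeps_single_stem():
    seq = "GGGGAAAGGGGAAAACCCCCCCC"
    db_ = "((((...((((....))))))))"
    dec = st.decompose_hairpin(_fold_from_db(seq, db_))
    assert dec.is_single_stem


# -------------------------------------------------------------- duplex rules

def _canonical_hairpin():
    """Mature M[0..20] on the 5' arm; last two mature bases unpaired in the
    loop region; star carries a 2-nt unpaired 3' tail."""
    mature = "GCGCGCGCAUAUGCGCGCGCA"             # 21 nt
    loop = "AAACAAAA"
    star = revcomp(mature[:-2]).replace("T", "U")
    seq = mature + loop + star + "AA"
    n = len(seq)
    partner = [-1] * n
    for i in range(19):                          # M[0..18] paired
        j = len(mature) + len(loop) + (18 - i)
        partner[i], partner[j] = j, i
    return seq, tuple(partner), (0, 20)


def test_duplex_overhang_canonical_two_two():
    seq, partner, mature = _canonical_hairpin()
    dec = st.decompose_hairpin(st.FoldResult(seq, st.pairs_to_dotbracket(
        len(seq), partner), -30.0, partner))
    assert dec.is_single_stem
    star, o5, o3 = st.duplex_overhang(mature, dec, window_end=len(seq) - 1)
    assert (o5, o3) == (2, 2)
    assert star[1] - star[0] + 1 == 21


def test_duplex_overhang_shifted_mature_breaks_symmetry():
    seq, partner, _ = _canonical_hairpin()
    dec = st.decompose_hairpin(st.FoldResult(seq, st.pairs_to_dotbracket(
        len(seq), partner), -30.0, partner))
    _star, o5, o3 = st.duplex_overhang((1, 21), dec,
                                       window_end=len(seq) - 1)
    assert (o5, o3) != (2, 2)


def test_mature_in_loop_raises_geometry_error():
    seq, partner, _ = _canonical_hairpin()
    dec = st.decompose_hairpin(st.FoldResult(seq, st.pairs_to_dotbracket(
        len(seq), partner), -30.0, partner))
    with pytest.raises(st.GeometryError):
        st.duplex_overhang((21, 27), dec)        # entirely unpaired loop


def test_max_defect_perfect_bulge_and_internal_loop():
    seq, partner, mature = _canonical_hairpin()
    assert st.max_defect(mature, None, partner) == (0, 0)

    # inject a 4-nt bulge on the star arm between mature pairs 9 and 10
    p = list(partner)
    for i in range(10, 19):                      # shift star partners by 4
        j = p[i]
        p[i] = j - 4
        p[j] = -1
        p[j - 4] = i
    assert st.max_defect(mature, None, tuple(p))[1] == 4

    # symmetric 3x3 internal loop: unpair mature 9..11 and their partners
    q = list(partner)
    for i in (9, 10, 11):
        j = q[i]
        q[i] = -1
        q[j] = -1
    loop, bulge = st.max_defect(mature, None, tuple(q))
    assert (loop, bulge) == (3, 0)
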