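"""Known-miRNA alignment, the temporary family database and quantification."""

import random

import pandas as pd
import pytest

from sporomir import known as kn
from sporomir import preprocess as pp


def _mk_table(rows, libs=("CK-1", "LT-1")):
    from collections import Counter
    counters = {lib: Counter() for lib in libs}
    for tag, counts in rows.items():
        for lib, c in zip(libs, counts):
            if c:
                counters[lib][tag] = c
    return pp.TagTable.from_counters(counters)


def _mutate(seq, k, rng):
    s = list(seq)
    for i in rng.sample(range(len(seq)), k):
        s[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[i]]
    return "".join(s)


RNG = random.Random(13)
M1 = "".join(RNG.choice("ACGT") for _ in range(21))
M2 = "".join(RNG.choice("ACGT") for _ in range(21))
REF = kn.MatureRef([("csn-miR100a", "miR100", M1),
                    ("csn-miR100b", "miR100", _mutate(M1, 2, RNG)),
                    ("csn-miR200a", "miR200", M2)])


def test_align_matches_brute_force_hamming_scan():
    rng = random.Random(21)
    matures = [(f"m{i}", "".join(rng.choice("ACGT") for _ in range(21)))
               for i in range(50)]
    ref = kn.MatureRef([(mid, "fam" + mid, seq) for mid, seq in matures])
    tags = [_mutate(matures[i % 50][1], rng.randint(0, 4), rng)
            for i in range(100)]
    table = _mk_table({t: (1, 0) for t in dict.fromkeys(tags)})
    hits = kn.align_tags(table, ref, max_mm=2)
    got = {(r.tag, r.mirna_id) for r in hits.itertuples()}
    expected = {(t, mid) for t in table.tags for mid, seq in matures
                if len(t) == len(seq)
                and sum(a != b for a, b in zip(t, seq)) <= 2}
    assert got == expected


def test_exact_hit_and_over_threshold_miss():
    tags = {M1: (5, 0), _mutate(M1, 3, random.Random(0)): (9, 9)}
    hits = kn.align_tags(_mk_table(tags), REF, 2)
    assert set(hits.tag) == {M1}
    assert hits.loc[hits.tag == M1, "mismatches"].min() == 0


def test_temp_db_picks_highest_expressed_member_per_family():
    tags = {M1: (100, 0), M2: (7, 0)}
    table = _mk_table(tags)
    hits = kn.align_tags(table, REF, 2)
    db = kn.build_temp_db(hits, table, REF)
    assert set(db.family) == {"miR100", "miR200"}
    assert db.set_index("family").loc["miR100", "mirna_id"] == "csn-miR100a"


def test_temp_db_tie_breaks_to_smaller_id():
    seq = M1
    ref = kn.MatureRef([("csn-miR300b", "miR300", seq),
                        ("csn-miR300a", "miR300", seq)])
    table = _mk_table({seq: (50, 0)})
    hits = kn.align_tags(table, ref, 2)
    db = kn.build_temp_db(hits, table, ref)
    assert db.mirna_id.tolist() == ["csn-miR300a"]


def test_quantify_assigns_each_tag_once_to_fewest_mismatches():
    rng = random.Random(3)
    tag_near_2 = _mutate(M2, 1, rng)
    table = _mk_table({M1: (5, 0), tag_near_2: (0, 9)})
    hits = kn.align_tags(table, REF, 2)
    db = kn.build_temp_db(hits, table, REF)
    profiles, assignment = kn.quantify(table, db, 2)
    assert profiles.loc["csn-miR100a"].tolist() == [5, 0]
    assert profiles.loc["csn-miR200a"].tolist() == [0, 9]
    # single assignment: totals never exceed the table
    assert profiles.values.sum() <= table.df.values.sum()
    assert assignment.tag.is_unique


def test_quantify_totals_match_assignment_oracle():
    rng = random.Random(31)
    tags = {}
    for i in range(30):
        base = M1 if i % 2 else M2
        tags[_mutate(base, rng.randint(0, 3), rng)] = (rng.randint(0, 9),
                                                       rng.randint(0, 9))
    table = _mk_table(tags)
    hits = kn.align_tags(table, REF, 2)
    if hits.empty:
        pytest.skip("randomly no hits")
    db = kn.build_temp_db(hits, table, REF)
    profiles, _ = kn.quantify(table, db, 2)
    # oracle: brute-force best representative per tag
    expect = {mid: [0, 0] for mid in db.mirna_id}
    for tag in table.tags:
        best = None
        for mid, seq in zip(db.mirna_id, db.mature_seq):
            if len(seq) != len(tag):
                continue
            mm = sum(a != b for a, b in zip(tag, seq))
            if mm <= 2 and (best is None or (mm, mid) < best):
                best = (mm, mid)
        if best:
            for k in (0, 1):
                expect[best[1]][k] += table.df.loc[tag].iloc[k]
    for mid, (a, b) in expect.items():
        assert profiles.loc[mid].tolist() == [a, b]


def test_raising_max_mm_never_loses_mirnas():
    rng = random.Random(8)
    tags = {_mutate(M1, 1, rng): (8, 0), M2: (4, 4)}
    table = _mk_table(tags)
    recovered = {}
    for mm in (0, 1, 2):
        hits = kn.align_tags(table, REF, mm)
        recovered[mm] = set(hits.mirna_id)
    assert recovered[0] <= recovered[1] <= recovered[2]


def test_unlocatable_mature_keeps_catalogue_evidence():
    genome = {"chr0": "ACACAC" * 200}
    db = pd.DataFrame({"family": ["miRX"], "mirna_id": ["csn-miRXa"],
                       "mature_seq": [M1], "support": [1.0]})
    profiles = pd.DataFrame([[3, 3]], index=["csn-miRXa"],
                            columns=["CK-1", "LT-1"])
    out = kn.validate_precursor(profiles, db, genome)
    assert bool(out.loc["csn-miRXa", "validated"])
    assert out.loc["csn-miRXa", "locus"] == ""


def test_structureless_locus_is_flagged_pseudo():
    mature = "ACCACACAACCCACAACACCA"             # A/C only: cannot pair
    genome = {"chr0": "CA" * 120 + mature + "AC" * 120}
    db = pd.DataFrame({"family": ["miRY"], "mirna_id": ["csn-miRYa"],
                       "mature_seq": [mature], "support": [1.0]})
    profiles = pd.DataFrame([[9, 0]], index=["csn-miRYa"],
                            columns=["CK-1", "LT-1"])
    out = kn.validate_precursor(profiles, db, genome)
    assert not bool(out.loc["csn-miRYa", "validated"])
    assert "unfoldable" in out.loc["csn-miRYa", "locus"]


@pytest.mark.parametrize("mid,family", [
    ("csn-miR1000a", "miR1000"),
    ("ath-miR156a-5p", "miR156"),
    ("miR398", "miR398"),
])
def test_family_derivation(mid, family):
    assert kn.derive_family(mid) == family


def test_duplicate_catalogue_ids_rejected():
    with pytest.raises(ValueError):
        kn.MatureRef([("a", "f", M1), ("a", "f", M2)])
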