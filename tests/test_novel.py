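"""Novel-miRNA prediction: windows, criteria, clustering, negative controls."""

from collections import Counter

import pandas as pd
import pytest

from sporomir import novel as nv
from sporomir import preprocess as pp
from sporomir import structure as st
from sporomir.seqio import revcomp
from conftest import DECOY_EXPECTED_FAIL


def test_window_excision_count_and_determinism():
    params = nv.NovelParams(flank_max=60, window_steps=15)
    wins = nv.excise_candidates((300, 320), 1000, params)
    assert len(wins) == 25                         # 5 x 5 flank combinations
    assert wins == nv.excise_candidates((300, 320), 1000, params)
    sizes = [we - ws + 1 for ws, we, _ in wins]
    assert sizes == sorted(sizes)
    assert all(ws <= 300 and we >= 320 for ws, we, _ in wins)


def test_window_clipping_at_contig_edge_is_flagged():
    params = nv.NovelParams(flank_max=60, window_steps=15)
    wins = nv.excise_candidates((5, 25), 100, params)
    assert any(trunc for _, _, trunc in wins)
    assert all(ws >= 0 and we <= 99 for ws, we, _ in wins)


def test_mapping_finds_both_strands_and_misses_absent_tags():
    genome = {"c1": "AC" * 50 + "ACGTGCATCGATCGGATCAGCA" + "CA" * 50}
    tag = "ACGTGCATCGATCGGATCAGCA"
    table = pp.TagTable.from_counters(
        {"CK-1": Counter({tag: 5, revcomp(tag): 4,
                          "TTTTGGGGCCCCAAAATTTTGG": 3})})
    loci = nv.map_unannotated(table, genome)
    by_tag = loci.groupby("tag")["strand"].agg(list)
    assert by_tag[tag] == ["+"]
    assert by_tag[revcomp(tag)] == ["-"]
    assert "TTTTGGGGCCCCAAAATTTTGG" not in by_tag.index


def test_planted_novels_recovered_with_correct_counts(small_sim):
    planted = small_sim.truth.planted("novel").set_index("mature_seq")
    recovered = {c.mature: c for c in small_sim.calls}
    assert set(planted.index) <= set(recovered)
    for mature, row in planted.iterrows():
        call = recovered[mature]
        assert call.accepted
        assert call.contig == row.contig and call.strand == row.strand
        # per-library counts equal the cleaned tag counts by construction
        tab = small_sim.kept.df.loc[mature]
        assert all(call.counts[lib] == int(tab[lib])
                   for lib in small_sim.kept.libraries)


def test_accepted_calls_are_sound_when_rechecked_from_scratch(small_sim):
    """Re-deriving every verdict from the stored precursor window must
    reproduce acceptance (no stale or inconsistent verdicts)."""
    params = nv.NovelParams()
    for call in small_sim.calls:
        seq = call.precursor_seq
        if call.strand == "-":
            pass  # precursor_seq is already in mature orientation
        m_rel = seq.find(call.mature)
        assert m_rel >= 0
        ev = nv.evaluate_candidate(seq,
                                   (m_rel, m_rel + len(call.mature) - 1),
                                   call.total_count, params)
        assert ev.accepted
        assert ev.verdicts == call.verdicts


def test_each_decoy_class_fails_exactly_its_criterion(small_sim):
    verdicts = small_sim.verdicts
    for _, row in small_sim.truth.planted("decoy").iterrows():
        rows = verdicts[verdicts.tag == row.mature_seq]
        assert len(rows) >= 1, row.decoy_class
        for _, v in rows.iterrows():
            fails = [c for c in nv.CRITERIA if v[f"crit_{c}"] == False]  # noqa: E712
            assert fails == [DECOY_EXPECTED_FAIL[row.decoy_class]], \
                (row.decoy_class, fails)
            assert not v.accepted


def test_lowering_min_count_never_removes_calls(small_sim):
    loose = nv.NovelParams(min_count=1)
    calls_loose, _ = nv.call_novel(small_sim.kept, small_sim.genome, loose,
                                   set(small_sim.assignment.tag))
    strict_matures = {c.mature for c in small_sim.calls}
    loose_matures = {c.mature for c in calls_loose}
    assert strict_matures <= loose_matures


def test_tightening_energy_threshold_shrinks_the_call_set(small_sim):
    tight = nv.NovelParams(energy_max=-40.0)
    calls_tight, _ = nv.call_novel(small_sim.kept, small_sim.genome, tight,
                                   set(small_sim.assignment.tag))
    assert {c.mature for c in calls_tight} <= {c.mature
                                               for c in small_sim.calls}


def test_identical_mature_at_two_loci_reported_once(small_sim):
    row = small_sim.truth.planted("novel").iloc[0]
    pre = row.precursor
    pad = "AC" * 100
    genome = {"dup": pad + pre + pad + pre + pad}
    table = pp.TagTable.from_counters(
        {"CK-1": Counter({row.mature_seq: 10})})
    calls, verdicts = nv.call_novel(table, genome, nv.NovelParams())
    assert len(calls) == 1
    assert len(calls[0].loci) == 2
    assert calls[0].novel_id == "novel_mir_1"


def test_support_counts_are_per_tag_not_per_locus(small_sim):
    """A mature at two loci with 3 total reads stays below min_count=5."""
    row = small_sim.truth.planted("novel").iloc[1]
    pad = "AC" * 100
    genome = {"dup": pad + row.precursor + pad + row.precursor + pad}
    table = pp.TagTable.from_counters(
        {"CK-1": Counter({row.mature_seq: 3})})
    calls, verdicts = nv.call_novel(table, genome, nv.NovelParams())
    assert calls == []
    assert (verdicts.crit_support == False).all()  # noqa: E712


def test_empty_unannotated_set_returns_no_calls(small_sim):
    table = pp.TagTable.from_counters({"CK-1": Counter()})
    calls, verdicts = nv.call_novel(table, small_sim.genome,
                                    nv.NovelParams())
    assert calls == [] and len(verdicts) == 0


def test_ids_follow_descending_total_count(small_sim):
    totals = [c.total_count for c in small_sim.calls]
    assert totals == sorted(totals, reverse=True)
    assert [c.novel_id for c in small_sim.calls] == \
        [f"novel_mir_{i}" for i in range(1, len(small_sim.calls) + 1)]


def test_energy_boundary_is_inclusive():
    params = nv.NovelParams()
    fr = st.FoldResult("A" * 30, "." * 30, -18.0, tuple([-1] * 30))
    # criterion check is on the evaluated fold energy; emulate via direct
    # comparison used in evaluate_candidate
    assert fr.energy <= params.energy_max
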