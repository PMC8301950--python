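"""Complementarity expectation scoring, site scanning and inhibition mode."""

import numpy as np
import pytest

from sporomir import targets as tg
from sporomir.seqio import revcomp

CFG = tg.ScoringConfig()
MATURE = "TGACAGAAGAGAGTGAGCACA"                 # 21 nt, G at pos 15


def _site_with_edit(mature, pos, new_base):
    site = list(revcomp(mature))
    site[len(mature) - pos] = new_base
    return "".join(site)


def test_perfect_reverse_complement_scores_zero():
    aln = tg.score_alignment(MATURE, revcomp(MATURE), CFG)
    assert aln.expectation == 0.0
    assert set(aln.pair_aln) == {"|"}


def test_non_seed_gu_wobble_costs_half():
    assert MATURE[14] == "G"                      # position 15, non-seed
    site = _site_with_edit(MATURE, 15, "T")       # G:U wobble
    aln = tg.score_alignment(MATURE, site, CFG)
    assert aln.expectation == 0.5
    assert tg.ungapped_score(MATURE, site, CFG) == 0.5


def test_seed_mismatch_costs_double():
    base = MATURE[2]                              # position 3, in the seed
    site = _site_with_edit(MATURE, 3, base)       # X:X mismatch
    aln = tg.score_alignment(MATURE, site, CFG)
    assert aln.expectation == 2.0
    # identical edit outside the seed costs exactly half
    site2 = _site_with_edit(MATURE, 13, MATURE[12])
    assert tg.score_alignment(MATURE, site2, CFG).expectation == 1.0


def test_dp_equals_exhaustive_ungapped_oracle():
    rng = np.random.default_rng(17)
    bases = np.array(list("ACGT"))
    for _ in range(200):
        m = "".join(rng.choice(bases, rng.integers(19, 23)))
        w = "".join(rng.choice(bases, len(m) + rng.integers(0, 4)))
        aln = tg.score_alignment(m, w, CFG, gaps=False)
        oracle = min(tg.ungapped_score(m, w[s:s + len(m)], CFG)
                     for s in range(len(w) - len(m) + 1))
        assert abs(aln.expectation - oracle) < 1e-9


def test_single_target_bulge_costs_gap_open():
    site = revcomp(MATURE)
    bulged = site[:8] + "C" + site[8:]
    aln = tg.score_alignment(MATURE, bulged, CFG)
    assert aln.expectation == CFG.gap_open
    assert "-" in aln.mirna_aln


def test_added_mismatches_never_lower_the_score():
    site = revcomp(MATURE)
    prev = 0.0
    for pos in (13, 15, 17):
        site = _site_with_edit(
            "".join(MATURE), pos, MATURE[pos - 1]) if pos == 13 else site
        # apply cumulatively
    score = 0.0
    site = list(revcomp(MATURE))
    for pos in (13, 15, 17):
        site[len(MATURE) - pos] = MATURE[pos - 1]
        new = tg.score_alignment(MATURE, "".join(site), CFG).expectation
        assert new >= score
        score = new


def test_short_site_yields_no_score():
    assert tg.score_alignment(MATURE, "ACGTACGTACGTACGTAA", CFG) is None


def test_scan_reports_planted_site_only():
    rng = np.random.default_rng(5)
    tr = "".join(rng.choice(list("ACGT"), 400))
    site = revcomp(MATURE)
    tr = tr[:150] + site + tr[150 + len(site):]
    mods = tg.scan_transcript(MATURE, tr, CFG, "m", "g")
    exact = [m for m in mods if m.expectation == 0.0]
    assert len(exact) == 1
    assert exact[0].site_start == 151
    assert exact[0].site_end == 151 + len(site) - 1
    assert exact[0].mode == "cleavage"


def test_scan_two_identical_sites_reports_both_leftmost_first():
    rng = np.random.default_rng(6)
    tr = "".join(rng.choice(list("ACGT"), 500))
    site = revcomp(MATURE)
    tr = tr[:50] + site + tr[50 + len(site):300] + site + tr[300 + len(site):]
    mods = [m for m in tg.scan_transcript(MATURE, tr, CFG)
            if m.expectation == 0.0]
    assert len(mods) == 2
    assert mods[0].site_start < mods[1].site_start


def test_scan_empty_when_nothing_beats_cutoff():
    rng = np.random.default_rng(7)
    tr = "".join(rng.choice(list("ACGT"), 300))
    strict = tg.ScoringConfig(cutoff=0.0)
    assert tg.scan_transcript(MATURE, tr, strict) == []


@pytest.mark.parametrize("score", [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
def test_designed_sites_rescore_exactly(score):
    rng = np.random.default_rng(int(score * 2))
    site = tg.build_site(MATURE, score, "cleavage", CFG, rng)
    aln = tg.score_alignment(MATURE, site, CFG)
    assert aln.expectation == score
    assert tg.classify_mode(aln, CFG) == "cleavage"


@pytest.mark.parametrize("score", [1.0, 2.0, 3.0])
def test_designed_translation_inhibition_round_trips(score):
    site = tg.build_site(MATURE, score, "translation_inhibition", CFG)
    aln = tg.score_alignment(MATURE, site, CFG)
    assert aln.expectation == score
    assert tg.classify_mode(aln, CFG) == "translation_inhibition"


def test_translation_inhibition_needs_a_central_defect():
    with pytest.raises(tg.TargetDesignError):
        tg.build_site(MATURE, 0.0, "translation_inhibition", CFG)
    with pytest.raises(tg.TargetDesignError):
        tg.build_site(MATURE, 0.75, "cleavage", CFG)     # not a half step


def test_mode_rule_checks_only_central_positions():
    site10 = _site_with_edit(MATURE, 10, MATURE[9])
    site15 = _site_with_edit(MATURE, 15, MATURE[14])
    a10 = tg.score_alignment(MATURE, site10, CFG)
    a15 = tg.score_alignment(MATURE, site15, CFG)
    assert tg.classify_mode(a10, CFG) == "translation_inhibition"
    assert tg.classify_mode(a15, CFG) == "cleavage"
    # a central G:U wobble still pairs -> cleavage
    mature_g10 = MATURE[:9] + "G" + MATURE[10:]
    gu10 = _site_with_edit(mature_g10, 10, "T")
    assert tg.classify_mode(tg.score_alignment(mature_g10, gu10, CFG),
                            CFG) == "cleavage"


def test_predict_targets_summary_counts(small_sim):
    from sporomir import simulate as sim
    transcripts, planted = sim.generate_transcriptome(
        small_sim.truth, None, small_sim.cfg)
    dems = {t.mirna_id: dict(zip(small_sim.truth.mirnas.mirna_id,
                                 small_sim.truth.mirnas.mature_seq))
            [t.mirna_id] for t in planted}
    table, summary = tg.predict_targets(dems, transcripts, CFG)
    assert summary["n_modules"] == len(table) >= len(planted)
    assert summary["n_cleavage"] + summary["n_translation_inhibition"] \
        == summary["n_modules"]
    # every planted site is recovered with its designed score and mode
    idx = table.set_index(["mirna_id", "gene_id", "site_start"])
    for t in planted:
        row = idx.loc[(t.mirna_id, t.gene_id, t.site_start)]
        assert float(row.expectation) == t.designed_score
        assert row["mode"] == t.designed_mode
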