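"""The synthetic-data generator: determinism, conservation, planted design."""

import numpy as np
import pytest

from sporomir import enrich as en
from sporomir import qpcr as qp
from sporomir import simulate as sim


def test_seed_determinism_genome_and_reads(small_sim):
    cfg = sim.SimConfig(seed=small_sim.cfg.seed, n_planted_known=8,
                        n_planted_novel=5, reads_per_library=20_000,
                        n_background_tags=500)
    genome2, truth2 = sim.generate_genome(cfg)
    assert genome2 == small_sim.genome
    assert truth2.mirnas.equals(small_sim.truth.mirnas)
    assert truth2.catalogue == small_sim.truth.catalogue
    records2, counts2 = sim.simulate_libraries(truth2, cfg)
    assert records2 == small_sim.records
    assert counts2.equals(small_sim.truth_counts)


def test_different_seeds_differ():
    cfg = sim.SimConfig(seed=99, n_planted_known=2, n_planted_novel=1,
                        n_decoy_hairpins=0, reads_per_library=2000,
                        n_background_tags=50, genome_length=12_000)
    g1, _ = sim.generate_genome(cfg)
    cfg2 = sim.SimConfig(seed=100, n_planted_known=2, n_planted_novel=1,
                         n_decoy_hairpins=0, reads_per_library=2000,
                         n_background_tags=50, genome_length=12_000)
    g2, _ = sim.generate_genome(cfg2)
    assert g1 != g2


def test_no_novel_no_decoys_leaves_only_known_truth():
    cfg = sim.SimConfig(seed=5, n_planted_known=3, n_planted_novel=0,
                        n_decoy_hairpins=0, genome_length=12_000,
                        n_background_tags=50)
    _, truth = sim.generate_genome(cfg)
    assert set(truth.mirnas.kind) == {"known"}


def test_config_validation():
    with pytest.raises(ValueError):
        sim.SimConfig(frac_polyA=0.5, frac_contaminant=0.6).validate()
    with pytest.raises(ValueError):
        sim.SimConfig(n_replicates=1).validate()
    with pytest.raises(ValueError):
        sim.SimConfig(conditions=("LT", "NO")).validate()


def test_genome_too_short_raises_sizing_error():
    cfg = sim.SimConfig(seed=1, n_planted_known=8, n_planted_novel=4,
                        genome_length=3_000)
    with pytest.raises(ValueError, match="too short"):
        sim.generate_genome(cfg)


def test_truth_counts_conserve_library_composition(small_sim):
    """Planted + background reads fill reads x (1 - junk fraction); the
    junk classes are binomial, so totals must sit within 3 sigma."""
    cfg = small_sim.cfg
    p_junk = sum(cfg.junk_fracs.values())
    N = cfg.reads_per_library
    for lib, recs in small_sim.records.items():
        total = sum(c for _, _, _, c in recs)
        assert total == N
        junk = sum(c for rid, _, _, c in recs
                   if any(tag in rid for tag in (":dimer", ":polyA", ":lq",
                                                 ":c")))
        sd = (N * p_junk * (1 - p_junk)) ** 0.5
        assert abs(junk - N * p_junk) <= 3 * sd


def test_planted_counts_track_condition_multipliers(small_sim):
    """A planted 4x LT effect appears as ~4x mean counts in LT."""
    truth = small_sim.truth.mirnas
    counts = small_sim.truth_counts
    strong = truth[(truth.mult_LT == 4.0) & (truth.kind != "decoy")
                   & (truth.base_abundance >= 100)]
    assert len(strong) >= 1
    for _, row in strong.iterrows():
        ck = counts.loc[row.mirna_id, ["CK-1", "CK-2", "CK-3"]].mean()
        lt = counts.loc[row.mirna_id, ["LT-1", "LT-2", "LT-3"]].mean()
        assert lt / max(ck, 1) > 2.0


def test_low_support_decoy_has_fixed_total_below_threshold(small_sim):
    row = small_sim.truth.mirnas[
        small_sim.truth.mirnas.decoy_class == "low_support"].iloc[0]
    total = small_sim.truth_counts.loc[row.mirna_id].sum()
    assert total == 4


def test_planted_targets_rescore_exactly(small_sim):
    from sporomir import targets as tg
    transcripts, planted = sim.generate_transcriptome(
        small_sim.truth, None, small_sim.cfg)
    assert len(planted) > 0
    seq_of = dict(zip(small_sim.truth.mirnas.mirna_id,
                      small_sim.truth.mirnas.mature_seq))
    cfg = tg.ScoringConfig()
    for t in planted[:10]:
        mature = seq_of[t.mirna_id]
        site = transcripts[t.gene_id][t.site_start - 1:
                                      t.site_start - 1 + len(mature)]
        aln = tg.score_alignment(mature, site, cfg)
        assert aln.expectation == t.designed_score
        assert tg.classify_mode(aln, cfg) == t.designed_mode


def test_empty_targets_spec_gives_clean_transcriptome(small_sim):
    from sporomir import targets as tg
    transcripts, planted = sim.generate_transcriptome(
        small_sim.truth, [], small_sim.cfg)
    assert planted == []
    cfg = tg.ScoringConfig()
    seqs = dict(zip(small_sim.truth.mirnas.mirna_id,
                    small_sim.truth.mirnas.mature_seq))
    some = list(transcripts.items())[:5]
    for mid, mature in list(seqs.items())[:5]:
        for gene, tr in some:
            assert tg.ungapped_scan(mature, tr, cfg) == []


def test_annotation_plants_one_enriched_term(small_sim):
    genes = [f"TEA{i:06d}.1" for i in range(1, 41)]
    designated = genes[:15]
    ann_df = sim.generate_annotation(genes, designated, small_sim.cfg)
    ann = en.Annotation(ann_df)
    rec = en.hypergeom_enrich(set(designated), ann)
    assert rec.iloc[0]["term"] == sim.ENRICHED_TERM
    assert rec.iloc[0]["p_adjust"] < 0.05


def test_ct_tables_encode_planted_fold_changes(small_sim):
    transcripts, planted = sim.generate_transcriptome(
        small_sim.truth, None, small_sim.cfg)
    ct_m, ct_t = sim.simulate_ct_tables(small_sim.truth, planted,
                                        small_sim.cfg)
    rel = qp.ddct(ct_m, "5.8S-rRNA", "CK")
    truth = small_sim.truth.mirnas.set_index("mirna_id")
    for assay in rel.assay.unique():
        mult_lt = truth.loc[assay, "mult_LT"]
        lt_mean = rel[(rel.assay == assay)
                      & (rel.condition == "LT")].rel_expr.mean()
        assert np.isclose(np.log2(lt_mean), np.log2(mult_lt), atol=0.8)


def test_background_tags_are_unique_and_length_distributed(small_sim):
    bg = small_sim.truth.background
    assert bg.tag.is_unique
    lengths = bg.tag.str.len()
    assert lengths.between(18, 30).all()
    mode = lengths.value_counts().idxmax()
    assert mode == 24


def test_length_distribution_shape_matches_design(small_sim):
    """The background small-RNA mass peaks at 24 nt with 21 nt second
    (the planted miRNAs, 20-22 nt, ride on top of this backdrop)."""
    from sporomir import preprocess as pp
    planted = set(small_sim.truth.mirnas.mature_seq)
    bg_table = small_sim.table.drop(planted)
    dist = pp.length_distribution(bg_table)
    tot = dist.groupby("length")["total"].sum().sort_values(ascending=False)
    assert tot.index[0] == 24
    assert tot.index[1] == 21
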