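"""Predict miRNA target genes and test term enrichment.

Scores each differential miRNA against a toy transcriptome with the
complementarity expectation schema (cutoff 3, seed 2-7 doubled), splits
modules into cleavage vs translation inhibition, and runs hypergeometric
GO/pathway enrichment on the target genes.
"""

from sporomir import enrich as en
from sporomir import simulate as sim
from sporomir import targets as tg

cfg = sim.SimConfig(seed=1, n_planted_known=10, n_planted_novel=5,
                    reads_per_library=20_000, n_background_tags=600)
_, truth = sim.generate_genome(cfg)
transcripts, planted_targets = sim.generate_transcriptome(truth, None, cfg)

dem_ids = {t.mirna_id for t in planted_targets}
matures = {mid: seq for mid, seq in zip(truth.mirnas.mirna_id,
                                        truth.mirnas.mature_seq)
           if mid in dem_ids}
table, summary = tg.predict_targets(matures, transcripts,
                                    tg.ScoringConfig())
print(f"target modules: {summary['n_modules']} "
      f"({summary['n_cleavage']} cleavage, "
      f"{summary['n_translation_inhibition']} translation inhibition) "
      f"across {summary['n_genes']} genes")
print(table.head(3)[["mirna_id", "gene_id", "site_start", "expectation",
                     "mode"]].to_string(index=False))
m = table.iloc[0]
print(f"\nalignment of {m.mirna_id} on {m.gene_id} "
      f"(miRNA 5'->3' over target 3'->5'):")
print(" ", m.mirna_aln, "\n ", m.pairing, "\n ", m.target_aln)

annotation = en.Annotation(sim.generate_annotation(
    list(transcripts), sorted({t.gene_id for t in planted_targets}), cfg))
rec = en.hypergeom_enrich(set(table.gene_id) & annotation.background,
                          annotation)
print("\ntop enriched terms (hypergeometric, BH-adjusted):")
print(rec.head(4)[["term", "name", "k", "K", "p_value", "p_adjust"]]
      .to_string(index=False))
print("\nA small adjusted p for the planted term shows the enrichment "
      "machinery recovers the designed functional signal.")
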