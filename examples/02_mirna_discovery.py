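"""Identify known miRNAs and predict novel ones from cleaned tags.

Runs contaminant removal, the temporary-database quantification of known
miRNAs, and hairpin-based novel-miRNA prediction, then compares the calls
against the planted truth.
"""

from sporomir import contaminants as ctm
from sporomir import known as kn
from sporomir import novel as nv
from sporomir import preprocess as pp
from sporomir import simulate as sim

cfg = sim.SimConfig(seed=1, n_planted_known=10, n_planted_novel=5,
                    reads_per_library=20_000, n_background_tags=600)
genome, truth = sim.generate_genome(cfg)
records, _ = sim.simulate_libraries(truth, cfg)
table, _ = pp.clean_libraries(records,
                              pp.CleanParams(adapter_seq=cfg.adapter_seq))

kept, removed = ctm.filter_ncrna(table, ctm.ContaminantDB(truth.contaminants))
print(f"contaminant filter: {len(removed)} tags removed "
      f"({removed['class'].value_counts().to_dict() if len(removed) else {}})")

profiles, temp_db, assignment = kn.identify_known(
    kept, kn.MatureRef(truth.catalogue), genome)
print(f"\nknown miRNAs: {len(profiles)} quantified, "
      f"{int(profiles.validated.sum())} with a foldable precursor "
      f"(pseudo-miRNAs excluded from downstream statistics)")
print(profiles.head(3).to_string())

calls, verdicts = nv.call_novel(kept, genome, nv.NovelParams(),
                                set(assignment.tag))
planted = set(truth.planted("novel").mature_seq)
print(f"\nnovel calls: {len(calls)}; planted novels recovered: "
      f"{sum(1 for c in calls if c.mature in planted)}/{len(planted)}")
for c in calls[:3]:
    print(f"  {c.novel_id}: {c.mature} @ {c.contig}:{c.mature_locus[0]}"
          f"({c.strand}), dG={c.energy:.1f} kcal/mol, "
          f"reads={c.total_count}")
decoys = set(truth.planted("decoy").mature_seq)
print(f"decoy hairpins accepted: {sum(1 for c in calls if c.mature in decoys)}"
      " (each decoy violates exactly one acceptance criterion)")
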