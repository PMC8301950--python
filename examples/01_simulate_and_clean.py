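"""Simulate a small pollen-tube small-RNA experiment and clean the reads.

Builds a toy genome with planted miRNA loci, draws raw FASTQ-style
libraries for 3 conditions x 3 replicates, runs the cleanup filters and
prints the per-class removal counts and the tag-length histogram.
"""

from sporomir import preprocess as pp
from sporomir import simulate as sim

cfg = sim.SimConfig(seed=1, n_planted_known=10, n_planted_novel=5,
                    reads_per_library=20_000, n_background_tags=600,
                    known_abundance_range=(30.0, 300.0))
genome, truth = sim.generate_genome(cfg)
records, truth_counts = sim.simulate_libraries(truth, cfg)
print(f"genome: {len(genome)} contigs, "
      f"{sum(len(s) for s in genome.values())} nt total")
print(f"planted: {len(truth.planted('known'))} known, "
      f"{len(truth.planted('novel'))} novel, "
      f"{len(truth.planted('decoy'))} decoys")

table, reports = pp.clean_libraries(
    records, pp.CleanParams(adapter_seq=cfg.adapter_seq))
rep = reports["CK-1"]
print(f"\nCK-1 cleanup: {rep.raw} raw -> {rep.clean} clean; removed "
      + ", ".join(f"{k}={v}" for k, v in rep.removed.items()))
print(f"unique tags across libraries: {len(table)}")

dist = pp.length_distribution(table)
tot = dist.groupby("length")["total"].sum()
print("\nlength histogram (reads):")
for length, count in tot.items():
    print(f"  {length:2d} nt  {'#' * (count // (tot.max() // 40 + 1))} {count}")
print("\nThe 24-nt mode with a 21-nt shoulder mirrors a typical plant "
      "small-RNA library, where 24-nt heterochromatic siRNAs dominate and "
      "21-nt miRNAs form the second peak.")
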