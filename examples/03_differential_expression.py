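"""Call differentially expressed miRNAs and partition them by treatment.

Normalises planted-truth counts to CPM, applies the |log2FC| > 1 and
p < 0.05 gate for low-temperature and nitric-oxide treatments vs control,
and prints the Venn partition of the two DEM sets.
"""

from sporomir import diffexpr as de
from sporomir import simulate as sim

cfg = sim.SimConfig(seed=1, n_planted_known=10, n_planted_novel=5,
                    reads_per_library=20_000, n_background_tags=600)
_, truth = sim.generate_genome(cfg)
_, counts = sim.simulate_libraries(truth, cfg)
counts = counts[counts.sum(axis=1) > 0]

matrix = de.normalize(counts)
dems_lt = de.call_dems(matrix, "LT", "CK")
dems_no = de.call_dems(matrix, "NO", "CK")
for name, d in (("LT/CK", dems_lt), ("NO/CK", dems_no)):
    up = ((d.is_dem) & (d.direction == "up")).sum()
    down = ((d.is_dem) & (d.direction == "down")).sum()
    print(f"{name}: {d.is_dem.sum()} DEMs ({up} up, {down} down) "
          f"of {len(d)} tested")

part = de.venn_partition(dems_lt, dems_no)
c = part["counts"]
print(f"\nVenn partition: LT-only {c['a_only']}, NO-only {c['b_only']}, "
      f"co-regulated {c['co']} ({c['co_concordant']} concordant)")
print("\ntop LT/CK records:")
print(dems_lt.head(5)[["mirna_id", "log2fc", "p_value", "is_dem"]]
      .to_string(index=False))
print("\nA co-regulated, direction-concordant set suggests the two "
      "treatments act through a shared regulatory axis.")
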