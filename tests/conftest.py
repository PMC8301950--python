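"""Shared fixtures: one reduced-scale simulated experiment, run once per
session and reused by the module tests and the invariant checks."""

from dataclasses import dataclass

import pytest

from sporomir import contaminants as ctm
from sporomir import known as kn
from sporomir import novel as nv
from sporomir import preprocess as pp
from sporomir import simulate as sim

DECOY_EXPECTED_FAIL = {
    "no_hairpin": "hairpin", "mature_in_loop": "one_arm",
    "shifted_star": "overhang", "big_bulge": "defects",
    "weak_energy": "energy", "low_support": "support",
}


@dataclass
class SimRun:
    cfg: sim.SimConfig
    genome: dict
    truth: sim.Truth
    records: dict
    truth_counts: object
    table: pp.TagTable
    reports: dict
    kept: pp.TagTable
    removed: object
    profiles: object
    temp_db: object
    assignment: object
    calls: list
    verdicts: object


def run_small_experiment(seed: int = 1, **overrides) -> SimRun:
    cfg = sim.SimConfig(seed=seed, n_planted_known=8, n_planted_novel=5,
                        reads_per_library=20_000, n_background_tags=500,
                        **overrides)
    genome, truth = sim.generate_genome(cfg)
    records, truth_counts = sim.simulate_libraries(truth, cfg)
    table, reports = pp.clean_libraries(
        records, pp.CleanParams(adapter_seq=cfg.adapter_seq))
    kept, removed = ctm.filter_ncrna(
        table, ctm.ContaminantDB(truth.contaminants), 0)
    profiles, temp_db, assignment = kn.identify_known(
        kept, kn.MatureRef(truth.catalogue), genome)
    calls, verdicts = nv.call_novel(kept, genome, nv.NovelParams(),
                                    set(assignment.tag))
    return SimRun(cfg, genome, truth, records, truth_counts, table, reports,
                  kept, removed, profiles, temp_db, assignment, calls,
                  verdicts)


@pytest.fixture(scope="session")
def small_sim() -> SimRun:
    return run_small_experiment(seed=1)
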