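"""End-to-end orchestration of the analysis stages.

Stages run in dependency order (simulate -> preprocess -> filter -> known
-> novel -> de -> targets -> enrich -> qpcr); each writes its outputs and
a JSON summary under ``outdir/<stage>/`` and is skipped on re-runs with an
unchanged configuration unless forced.  One top-level seed derives every
stage's randomness, so two runs from the same configuration produce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import contaminants as ctm
from . import diffexpr as de
from . import enrich as en
from . import known as kn
from . import novel as nv
from . import preprocess as pp
from . import qpcr as qp
from . import simulate as sim
from . import targets as tg
from .seqio import read_fasta, read_fasta_with_desc

log = logging.getLogger("sporomir")

STAGES = ("simulate", "preprocess", "filter", "known", "novel", "de",
          "targets", "enrich", "qpcr")

DEPENDS = {
    "simulate": (),
    "preprocess": ("simulate",),
    "filter": ("preprocess", "simulate"),
    "known": ("filter", "simulate"),
    "novel": ("known",),
    "de": ("known", "novel"),
    "targets": ("de", "simulate"),
    "enrich": ("targets", "simulate"),
    "qpcr": ("simulate",),
}


class DependencyError(RuntimeError):
    pass


@dataclasses.dataclass
class RunConfig:
    """Paths, seeds and per-stage parameter blocks for a pipeline run."""

    outdir: str = "sporomir_run"
    seed: int = 1
    sim: sim.SimConfig = dataclasses.field(default_factory=sim.SimConfig)
    clean: pp.CleanParams = dataclasses.field(default_factory=pp.CleanParams)
    novel: nv.NovelParams = dataclasses.field(default_factory=nv.NovelParams)
    scoring: tg.ScoringConfig = dataclasses.field(
        default_factory=tg.ScoringConfig)
    contaminant_max_mm: int = 0
    known_max_mm: int = 2
    lfc_threshold: float = 1.0
    alpha: float = 0.05

    def __post_init__(self):
        self.sim.seed = self.seed
        self.clean.adapter_seq = self.sim.adapter_seq

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        blocks = {"sim": sim.SimConfig, "clean": pp.CleanParams,
                  "novel": nv.NovelParams, "scoring": tg.ScoringConfig}
        kwargs = {}
        for key, val in raw.items():
            if key in blocks:
                kwargs[key] = blocks[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.md5(json.dumps(self.to_dict(), sort_keys=True,
                                      default=str).encode()).hexdigest()


class Pipeline:
    """Stateful runner: executes or reloads stages into a shared context."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.ctx: dict = {}
        self.summaries: dict = {}

    # ------------------------------------------------------------- plumbing
    def _stage_dir(self, stage: str) -> Path:
        d = self.outdir / stage
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _marker(self, stage: str) -> Path:
        return self.outdir / stage / ".stage.json"

    def _is_cached(self, stage: str) -> bool:
        marker = self._marker(stage)
        if not marker.exists():
            return False
        try:
            info = json.loads(marker.read_text())
        except json.JSONDecodeError:
            return False
        return info.get("config_hash") == self.config.digest()

    def _finish(self, stage: str, summary: dict, t0: float,
                cached: bool = False) -> None:
        summary = {**summary, "cached": cached,
                   "wall_s": round(time.time() - t0, 3)}
        self.summaries[stage] = summary
        self._marker(stage).write_text(json.dumps(
            {"config_hash": self.config.digest(), "summary": summary},
            indent=1, default=str))

    def run(self, stages: list[str] | None = None, force: bool = False
            ) -> dict:
        """Execute the requested stages (all by default) plus whatever
        cached upstream outputs they need; returns the run summary."""
        requested = list(stages or STAGES)
        for s in requested:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        needed: set[str] = set()

        def expand(s: str):
            for d in DEPENDS[s]:
                expand(d)
                needed.add(d)

        for s in requested:
            expand(s)
        for stage in STAGES:
            if stage in requested:
                if self._is_cached(stage) and not force:
                    log.info("stage %s: cached, skipping", stage)
                    t0 = time.time()
                    getattr(self, f"_load_{stage}")()
                    old = json.loads(self._marker(stage).read_text())
                    self._finish(stage, old["summary"], t0, cached=True)
                else:
                    log.info("stage %s: running", stage)
                    t0 = time.time()
                    summary = getattr(self, f"_run_{stage}")()
                    self._finish(stage, summary, t0)
            elif stage in needed and stage not in self.ctx.get("_loaded", set()):
                if not self._is_cached(stage):
                    raise DependencyError(
                        f"stage '{stage}' output missing or stale; run it "
                        f"before its dependents")
                getattr(self, f"_load_{stage}")()
        (self.outdir / "run_summary.json").write_text(
            json.dumps(self.summaries, indent=1, default=str))
        return self.summaries

    def _mark_loaded(self, stage: str) -> None:
        self.ctx.setdefault("_loaded", set()).add(stage)

    # ------------------------------------------------------------- simulate
    def _run_simulate(self) -> dict:
        cfg = self.config.sim
        out = self._stage_dir("simulate")
        genome, truth = sim.generate_genome(cfg)
        records, truth_counts = sim.simulate_libraries(truth, cfg, out)
        transcripts, planted_targets = sim.generate_transcriptome(
            truth, None, cfg)
        designated = sorted({t.gene_id for t in planted_targets})
        annotation = sim.generate_annotation(list(transcripts), designated,
                                             cfg)
        ct_m, ct_t = sim.simulate_ct_tables(truth, planted_targets, cfg)
        sim.write_reference_files(genome, truth, out)
        sim.write_fasta(out / "transcripts.fasta", transcripts.items())
        annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
        pd.DataFrame([dataclasses.asdict(t) for t in planted_targets]) \
            .to_csv(out / "planted_targets.tsv", sep="\t", index=False)
        ct_m.to_csv(out / "ct_mirna.tsv", sep="\t", index=False)
        ct_t.to_csv(out / "ct_targets.tsv", sep="\t", index=False)
        self.ctx.update(genome=genome, truth=truth, records=records,
                        truth_counts=truth_counts, transcripts=transcripts,
                        planted_targets=planted_targets,
                        annotation=annotation, ct_mirna=ct_m, ct_targets=ct_t)
        self._mark_loaded("simulate")
        return {"libraries": len(records),
                "reads_per_library": cfg.reads_per_library,
                "planted_known": cfg.n_planted_known,
                "planted_novel": cfg.n_planted_novel,
                "decoys": cfg.n_decoy_hairpins,
                "transcripts": len(transcripts)}

    def _load_simulate(self) -> None:
        out = self.outdir / "simulate"
        cfg = self.config.sim
        genome = read_fasta(out / "genome.fasta")
        mirnas = pd.read_csv(out / "truth_mirnas.tsv", sep="\t",
                             keep_default_na=False)
        catalogue = [(rid, desc.split("family=")[-1].split()[0], seq)
                     for rid, desc, seq in
                     read_fasta_with_desc(out / "mature_catalogue.fasta")]
        contams = ctm.ContaminantDB.from_fasta(out / "contaminants.fasta")
        truth = sim.Truth(mirnas, catalogue,
                          contams.records, pd.DataFrame(), cfg)
        ext = ".fastq.gz" if cfg.gzip_fastq else ".fastq"
        records = {lib: out / f"{lib}{ext}" for lib in cfg.libraries}
        planted = [sim.PlantedTarget(**r) for r in
                   pd.read_csv(out / "planted_targets.tsv", sep="\t")
                   .to_dict("records")]
        self.ctx.update(
            genome=genome, truth=truth, records=records,
            truth_counts=pd.read_csv(out / "truth_counts.tsv", sep="\t",
                                     index_col=0),
            transcripts=read_fasta(out / "transcripts.fasta"),
            planted_targets=planted,
            annotation=pd.read_csv(out / "annotation.tsv", sep="\t"),
            ct_mirna=pd.read_csv(out / "ct_mirna.tsv", sep="\t"),
            ct_targets=pd.read_csv(out / "ct_targets.tsv", sep="\t"))
        self._mark_loaded("simulate")

    # ----------------------------------------------------------- preprocess
    def _run_preprocess(self) -> dict:
        out = self._stage_dir("preprocess")
        table, reports = pp.clean_libraries(self.ctx["records"],
                                            self.config.clean)
        table.to_tsv(out / "tags.tsv")
        table.to_fasta(out / "tags.fasta")
        pp.write_reports(reports, out / "filter_report.json")
        lengths = pp.length_distribution(table)
        lengths.to_csv(out / "length_distribution.tsv", sep="\t", index=False)
        self.ctx.update(table=table, reports=reports)
        self._mark_loaded("preprocess")
        return {"unique_tags": len(table),
                "clean_reads": int(table.total_counts().sum()),
                "removed": {lib: r.to_dict() for lib, r in reports.items()}}

    def _load_preprocess(self) -> None:
        out = self.outdir / "preprocess"
        self.ctx["table"] = pp.TagTable.from_tsv(out / "tags.tsv")
        self.ctx["reports"] = json.loads(
            (out / "filter_report.json").read_text())
        self._mark_loaded("preprocess")

    # --------------------------------------------------------------- filter
    def _run_filter(self) -> dict:
        out = self._stage_dir("filter")
        db = ctm.ContaminantDB(self.ctx["truth"].contaminants)
        kept, removed = ctm.filter_ncrna(self.ctx["table"], db,
                                         self.config.contaminant_max_mm)
        kept.to_tsv(out / "kept.tsv")
        removed.rename_axis("tag").to_csv(out / "removed.tsv", sep="\t")
        self.ctx.update(kept=kept, removed=removed)
        self._mark_loaded("filter")
        return {"kept_tags": len(kept), "removed_tags": len(removed),
                "removed_reads": int(removed[self.ctx['table'].libraries]
                                     .values.sum()) if len(removed) else 0}

    def _load_filter(self) -> None:
        out = self.outdir / "filter"
        self.ctx["kept"] = pp.TagTable.from_tsv(out / "kept.tsv")
        self.ctx["removed"] = pd.read_csv(out / "removed.tsv", sep="\t",
                                          index_col="tag")
        self._mark_loaded("filter")

    # ---------------------------------------------------------------- known
    def _run_known(self) -> dict:
        out = self._stage_dir("known")
        ref = kn.MatureRef(self.ctx["truth"].catalogue)
        profiles, temp_db, assignment = kn.identify_known(
            self.ctx["kept"], ref, self.ctx["genome"],
            self.config.known_max_mm, self.config.novel)
        profiles.rename_axis("mirna_id").to_csv(out / "profiles.tsv",
                                                sep="\t")
        temp_db.to_csv(out / "temp_db.tsv", sep="\t", index=False)
        assignment.to_csv(out / "assignment.tsv", sep="\t", index=False)
        self.ctx.update(known_profiles=profiles, temp_db=temp_db,
                        known_assignment=assignment)
        self._mark_loaded("known")
        return {"known_mirnas": len(profiles),
                "validated": int(profiles.validated.sum())
                if len(profiles) else 0,
                "assigned_tags": len(assignment)}

    def _load_known(self) -> None:
        out = self.outdir / "known"
        self.ctx["known_profiles"] = pd.read_csv(
            out / "profiles.tsv", sep="\t", index_col="mirna_id",
            keep_default_na=False)
        self.ctx["known_profiles"]["validated"] = \
            self.ctx["known_profiles"]["validated"].astype(bool)
        self.ctx["temp_db"] = pd.read_csv(out / "temp_db.tsv", sep="\t")
        self.ctx["known_assignment"] = pd.read_csv(out / "assignment.tsv",
                                                   sep="\t")
        self._mark_loaded("known")

    # ---------------------------------------------------------------- novel
    def _run_novel(self) -> dict:
        out = self._stage_dir("novel")
        exclude = set(self.ctx["known_assignment"].tag)
        calls, verdicts = nv.call_novel(self.ctx["kept"], self.ctx["genome"],
                                        self.config.novel, exclude)
        libraries = self.ctx["kept"].libraries
        frame = nv.calls_to_frame(calls, libraries)
        frame.to_csv(out / "calls.tsv", sep="\t", index=False)
        verdicts.to_csv(out / "verdicts.tsv", sep="\t", index=False)
        nv.calls_to_gff3(calls, out / "novel.gff3")
        nv.precursors_to_fasta(calls, out / "precursors.fasta")
        self.ctx.update(novel_calls=calls, novel_frame=frame,
                        novel_verdicts=verdicts)
        self._mark_loaded("novel")
        return {"novel_mirnas": len(calls),
                "evaluated_loci": len(verdicts)}

    def _load_novel(self) -> None:
        out = self.outdir / "novel"
        self.ctx["novel_frame"] = pd.read_csv(out / "calls.tsv", sep="\t")
        self.ctx["novel_verdicts"] = pd.read_csv(out / "verdicts.tsv",
                                                 sep="\t")
        self.ctx["novel_calls"] = None      # only the frame is reloadable
        self._mark_loaded("novel")

    # ------------------------------------------------------------------- de
    def _counts_matrix(self) -> pd.DataFrame:
        prof = self.ctx["known_profiles"]
        libraries = [c for c in prof.columns
                     if c not in ("validated", "locus")]
        known_counts = prof.loc[prof.validated, libraries]
        nf = self.ctx["novel_frame"]
        if len(nf):
            novel_counts = nf.set_index("novel_id")[libraries]
        else:
            novel_counts = pd.DataFrame(columns=libraries)
        return pd.concat([known_counts, novel_counts]).astype(int)

    def _run_de(self) -> dict:
        out = self._stage_dir("de")
        counts = self._counts_matrix()
        matrix = de.normalize(counts)
        counts.rename_axis("mirna_id").to_csv(out / "raw_counts.tsv",
                                              sep="\t")
        matrix.cpm.rename_axis("mirna_id").to_csv(out / "cpm.tsv", sep="\t")
        conds = [c for c in self.config.sim.conditions if c != "CK"]
        dems = {}
        for cond in conds:
            d = de.call_dems(matrix, cond, "CK", self.config.lfc_threshold,
                             self.config.alpha)
            d.to_csv(out / f"dem_{cond}_CK.tsv", sep="\t", index=False)
            dems[cond] = d
        venn = {}
        if len(conds) >= 2:
            venn = de.venn_partition(dems[conds[0]], dems[conds[1]])
            (out / "venn.json").write_text(json.dumps(venn, indent=1))
        dem_ids = sorted(set().union(*[set(d.loc[d.is_dem, "mirna_id"])
                                       for d in dems.values()]))
        de.heatmap_matrix(matrix, dem_ids).rename_axis("mirna_id") \
            .to_csv(out / "heatmap.tsv", sep="\t")
        self.ctx.update(matrix=matrix, dems=dems, venn=venn, dem_ids=dem_ids)
        self._mark_loaded("de")
        return {"tested": len(matrix.cpm),
                "dems": {c: int(d.is_dem.sum()) for c, d in dems.items()},
                "co_regulated": venn.get("counts", {}).get("co", 0)}

    def _load_de(self) -> None:
        out = self.outdir / "de"
        raw = pd.read_csv(out / "raw_counts.tsv", sep="\t",
                          index_col="mirna_id")
        self.ctx["matrix"] = de.normalize(raw)
        conds = [c for c in self.config.sim.conditions if c != "CK"]
        self.ctx["dems"] = {c: pd.read_csv(out / f"dem_{c}_CK.tsv", sep="\t")
                            for c in conds}
        venn_path = out / "venn.json"
        self.ctx["venn"] = (json.loads(venn_path.read_text())
                            if venn_path.exists() else {})
        self.ctx["dem_ids"] = sorted(set().union(
            *[set(d.loc[d.is_dem, "mirna_id"])
              for d in self.ctx["dems"].values()]))
        self._mark_loaded("de")

    # -------------------------------------------------------------- targets
    def _dem_matures(self) -> dict[str, str]:
        matures = {}
        temp_db = self.ctx["temp_db"]
        seq_of = dict(zip(temp_db.mirna_id, temp_db.mature_seq))
        nf = self.ctx["novel_frame"]
        seq_of.update(dict(zip(nf.novel_id, nf.mature)) if len(nf) else {})
        for mid in self.ctx["dem_ids"]:
            if mid in seq_of:
                matures[mid] = seq_of[mid]
        return matures

    def _run_targets(self) -> dict:
        out = self._stage_dir("targets")
        table, summary = tg.predict_targets(self._dem_matures(),
                                            self.ctx["transcripts"],
                                            self.config.scoring)
        table.to_csv(out / "modules.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        self.ctx["target_table"] = table
        self._mark_loaded("targets")
        return summary

    def _load_targets(self) -> None:
        self.ctx["target_table"] = pd.read_csv(
            self.outdir / "targets" / "modules.tsv", sep="\t")
        self._mark_loaded("targets")

    # --------------------------------------------------------------- enrich
    def _run_enrich(self) -> dict:
        out = self._stage_dir("enrich")
        annotation = en.Annotation(self.ctx["annotation"])
        table = self.ctx["target_table"]
        summary = {}
        direction = {}
        for cond, d in self.ctx["dems"].items():
            for r in d[d.is_dem].itertuples():
                direction[r.mirna_id] = r.direction
        for cond, d in self.ctx["dems"].items():
            dem_ids = set(d.loc[d.is_dem, "mirna_id"])
            genes = set(table.loc[table.mirna_id.isin(dem_ids), "gene_id"])
            genes &= annotation.background
            if not genes:
                summary[cond] = {"terms": 0}
                continue
            rec = en.hypergeom_enrich(genes, annotation)
            rec.to_csv(out / f"enrichment_{cond}_CK.tsv", sep="\t",
                       index=False)
            if len(rec):
                tt, mt = en.build_networks(rec, table, direction)
                tt.to_csv(out / f"network_term_term_{cond}.tsv", sep="\t",
                          index=False)
                mt.to_csv(out / f"network_mirna_term_{cond}.tsv", sep="\t",
                          index=False)
            summary[cond] = {"selected_genes": len(genes), "terms": len(rec),
                             "significant":
                                 int((rec.p_adjust < 0.05).sum())
                                 if len(rec) else 0,
                             "top_term": rec.term.iloc[0] if len(rec) else ""}
            self.ctx[f"enrichment_{cond}"] = rec
        self._mark_loaded("enrich")
        return summary

    def _load_enrich(self) -> None:
        out = self.outdir / "enrich"
        for cond in [c for c in self.config.sim.conditions if c != "CK"]:
            p = out / f"enrichment_{cond}_CK.tsv"
            if p.exists():
                self.ctx[f"enrichment_{cond}"] = pd.read_csv(p, sep="\t")
        self._mark_loaded("enrich")

    # ----------------------------------------------------------------- qpcr
    def _run_qpcr(self) -> dict:
        out = self._stage_dir("qpcr")
        rel_m = qp.ddct(self.ctx["ct_mirna"], "5.8S-rRNA", "CK")
        rel_t = qp.ddct(self.ctx["ct_targets"], "beta-Actin", "CK")
        rel_m.to_csv(out / "mirna_relexpr.tsv", sep="\t", index=False)
        rel_t.to_csv(out / "target_relexpr.tsv", sep="\t", index=False)
        pair_of = {}
        for t in self.ctx["planted_targets"]:
            pair_of.setdefault(t.mirna_id, t.gene_id)
        rows = []
        for assay in rel_m.assay.unique():
            gene = pair_of.get(assay)
            if gene and gene in set(rel_t.assay):
                rows.append(qp.correlate(rel_m, rel_t, assay, gene))
        corr = pd.DataFrame(rows)
        corr.to_csv(out / "correlations.tsv", sep="\t", index=False)
        self.ctx.update(rel_mirna=rel_m, rel_target=rel_t, correlations=corr)
        self._mark_loaded("qpcr")
        inverse = int((corr.relationship == "inverse").sum()) if len(corr) else 0
        return {"assays": int(rel_m.assay.nunique()),
                "correlated_pairs": len(corr), "inverse_pairs": inverse}

    def _load_qpcr(self) -> None:
        out = self.outdir / "qpcr"
        self.ctx["rel_mirna"] = pd.read_csv(out / "mirna_relexpr.tsv",
                                            sep="\t")
        self.ctx["rel_target"] = pd.read_csv(out / "target_relexpr.tsv",
                                             sep="\t")
        self.ctx["correlations"] = pd.read_csv(out / "correlations.tsv",
                                               sep="\t")
        self._mark_loaded("qpcr")


def run_pipeline(config: RunConfig, stages: list[str] | None = None,
                 force: bool = False) -> dict:
    """Convenience wrapper: build a :class:`Pipeline` and run it."""
    return Pipeline(config).run(stages, force)
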