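"""Novel-miRNA prediction from genome-mapped unannotated tags.

A candidate locus is accepted when a precursor window around the mapped
tag satisfies all of: (1) it folds into a single-stem hairpin; (2) the
mature lies within one arm; (3) the mature/miRNA* duplex shows the
canonical 2-nt 3' overhangs on both strands; (4) the duplex is free of
large internal loops or bulges; (5) the hairpin is steady, with folding
energy <= -18 kcal/mol; and (6) the mature tag has at least 5 supporting
reads summed over libraries.  Criteria 2-5 are only evaluable on a
hairpin (and 3-4 only once the mature sits in an arm); verdicts that
cannot be evaluated are recorded as ``None`` so that each negative
control fails exactly its designated criterion.

Windows step outward from the mapped tag; the accepted window with the
lowest folding energy represents the locus (when none is accepted, the
lowest-energy window is reported for diagnosis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import structure
from .preprocess import TagTable
from .seqio import revcomp, write_fasta, write_gff3

CRITERIA = ("hairpin", "one_arm", "overhang", "defects", "energy", "support")


@dataclass
class NovelParams:
    """Tunable thresholds of the novel-miRNA criteria.

    ``flank_max``/``window_steps`` define the precursor search windows
    around a mapped tag (sized to compact plant-style toy precursors;
    widen for genomic data).  ``energy_max`` is inclusive: a hairpin at
    exactly -18 kcal/mol passes.  ``min_count`` applies to the tag's count
    summed across libraries, counted once even for multi-locus tags.
    """

    flank_max: int = 60
    window_steps: int = 15
    loop_max: int = 5
    bulge_max: int = 4
    energy_max: float = -18.0
    min_count: int = 5
    overhang_required: int = 2
    overhang_tol: int = 0
    mature_len_range: tuple[int, int] = (18, 26)
    map_len_range: tuple[int, int] = (18, 24)
    backend: str = "vienna"

    def validate(self) -> None:
        if self.energy_max >= 0:
            raise ValueError("energy_max must be negative")
        if self.flank_max < 0 or self.window_steps <= 0:
            raise ValueError("invalid window policy")


@dataclass
class CandidateEval:
    """Verdicts for one precursor window (True/False/None per criterion)."""

    verdicts: dict
    fold: structure.FoldResult
    window: tuple[int, int]                 # within the evaluated region
    star: tuple[int, int] | None
    truncated: bool = False

    @property
    def accepted(self) -> bool:
        return all(v is True for v in self.verdicts.values())

    @property
    def energy(self) -> float:
        return self.fold.energy


@dataclass
class NovelCall:
    novel_id: str
    mature: str
    star_seq: str
    contig: str
    strand: str
    mature_locus: tuple[int, int]           # genome, 1-based inclusive
    precursor_locus: tuple[int, int]
    energy: float
    verdicts: dict
    counts: dict
    accepted: bool
    precursor_seq: str = ""
    loci: list = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return int(sum(self.counts.values()))


# --------------------------------------------------------------- primitives

def map_unannotated(table: TagTable, genome: dict[str, str],
                    params: NovelParams | None = None) -> pd.DataFrame:
    """Exact-match loci (both strands, all occurrences) of unannotated tags.

    Only tags in the mapping length window (default 18-24 nt) are queried.
    Coordinates are 1-based inclusive on the plus strand.
    """
    from .known import locate_exact

    params = params or NovelParams()
    lo, hi = params.map_len_range
    rows = []
    for tag in table.tags:
        if not lo <= len(tag) <= hi:
            continue
        for contig, start, end, strand in locate_exact(tag, genome):
            rows.append((tag, contig, start, end, strand))
    return pd.DataFrame(rows, columns=["tag", "contig", "start", "end",
                                       "strand"])


def excise_candidates(mature: tuple[int, int], seq_len: int,
                      params: NovelParams) -> list[tuple[int, int, bool]]:
    """Candidate precursor windows around a mature interval (0-based).

    Flank sizes run 0..flank_max in steps of window_steps on each side;
    windows are clipped at sequence edges (flagged truncated), deduplicated
    and ordered by increasing size, 5'-flank first.
    """
    params.validate()
    s, e = mature
    steps = list(range(0, params.flank_max + 1, params.window_steps))
    seen = {}
    for f5 in steps:
        for f3 in steps:
            ws, we = max(0, s - f5), min(seq_len - 1, e + f3)
            truncated = (ws != s - f5) or (we != e + f3)
            key = (ws, we)
            if key not in seen:
                seen[key] = (we - ws + 1, f5, truncated)
    ordered = sorted(seen, key=lambda k: (seen[k][0], seen[k][1]))
    return [(ws, we, seen[(ws, we)][2]) for ws, we in ordered]


def evaluate_candidate(window_seq: str, mature: tuple[int, int],
                       counts_total: int, params: NovelParams
                       ) -> CandidateEval:
    """Apply every criterion to one excised window.

    ``mature`` is 0-based inclusive within ``window_seq``.  Structure-
    dependent verdicts cascade to ``None`` when their prerequisite fails
    (no hairpin -> no arms, no duplex, no hairpin energy).
    """
    fr = structure.fold(window_seq, params.backend)
    dec = structure.decompose_hairpin(fr)
    verdicts: dict = {c: None for c in CRITERIA}
    verdicts["hairpin"] = bool(dec.is_single_stem)
    star = None
    if dec.is_single_stem:
        verdicts["energy"] = fr.energy <= params.energy_max
        try:
            star, o5, o3 = structure.duplex_overhang(
                mature, dec, window_end=len(window_seq) - 1)
            verdicts["one_arm"] = True
            req, tol = params.overhang_required, params.overhang_tol
            verdicts["overhang"] = (abs(o5 - req) <= tol
                                    and abs(o3 - req) <= tol)
            loop, bulge = structure.max_defect(mature, star, dec.partner)
            verdicts["defects"] = (loop <= params.loop_max
                                   and bulge <= params.bulge_max)
        except structure.GeometryError:
            verdicts["one_arm"] = False
    verdicts["support"] = counts_total >= params.min_count
    return CandidateEval(verdicts, fr, (0, len(window_seq) - 1), star)


def evaluate_locus(region_seq: str, mature: tuple[int, int],
                   counts_total: int, params: NovelParams | None = None
                   ) -> CandidateEval:
    """Evaluate all windows around a mature within a region; return the
    best-accepted window (lowest energy) or, failing that, the most
    informative window — fewest failed criteria, then fewest unevaluable
    ones, then lowest energy — as the diagnostic representative."""
    params = params or NovelParams()
    best_acc: CandidateEval | None = None
    best_any: tuple[int, int, float, CandidateEval] | None = None
    for ws, we, trunc in excise_candidates(mature, len(region_seq), params):
        ev = evaluate_candidate(region_seq[ws:we + 1],
                                (mature[0] - ws, mature[1] - ws),
                                counts_total, params)
        ev.window = (ws, we)
        ev.truncated = trunc
        n_fail = sum(1 for v in ev.verdicts.values() if v is False)
        n_none = sum(1 for v in ev.verdicts.values() if v is None)
        key = (n_fail, n_none, ev.energy)
        if best_any is None or key < best_any[:3]:
            best_any = (*key, ev)
        if ev.accepted and (best_acc is None or ev.energy < best_acc.energy):
            best_acc = ev
    return best_acc or best_any[3]


def hairpin_context_ok(contig_seq: str, mature0: tuple[int, int], strand: str,
                       params: NovelParams) -> bool:
    """Does any window fold into a single-stem hairpin with the mature in
    one arm?  (Criteria 1-2 only — the known-miRNA pseudo test.)"""
    region, mat = _extract_region(contig_seq, mature0, strand, params)
    for ws, we, _ in excise_candidates(mat, len(region), params):
        ev = evaluate_candidate(region[ws:we + 1], (mat[0] - ws, mat[1] - ws),
                                counts_total=params.min_count, params=params)
        if ev.verdicts["hairpin"] and ev.verdicts["one_arm"]:
            return True
    return False


def _extract_region(contig_seq: str, mature0: tuple[int, int], strand: str,
                    params: NovelParams) -> tuple[str, tuple[int, int]]:
    """Cut the maximal window region around a locus; on the minus strand
    the region is reverse-complemented so the mature reads 5'->3'."""
    s, e = mature0
    rs = max(0, s - params.flank_max)
    re_ = min(len(contig_seq) - 1, e + params.flank_max)
    region = contig_seq[rs:re_ + 1]
    if strand == "-":
        region = revcomp(region)
        n = len(region)
        mat = (n - 1 - (e - rs), n - 1 - (s - rs))
    else:
        mat = (s - rs, e - rs)
    return region, mat


# ------------------------------------------------------------------- calling

def _merge_clusters(loci: pd.DataFrame) -> list[dict]:
    """Group mapped loci into clusters of overlapping intervals per
    (contig, strand)."""
    clusters = []
    for (contig, strand), grp in loci.groupby(["contig", "strand"]):
        grp = grp.sort_values(["start", "end"])
        cur = None
        for _, r in grp.iterrows():
            if cur is not None and r.start <= cur["end"]:
                cur["end"] = max(cur["end"], int(r.end))
                cur["members"].append((r.tag, int(r.start), int(r.end)))
            else:
                if cur is not None:
                    clusters.append(cur)
                cur = dict(contig=contig, strand=strand, start=int(r.start),
                           end=int(r.end),
                           members=[(r.tag, int(r.start), int(r.end))])
        if cur is not None:
            clusters.append(cur)
    return clusters


def call_novel(table: TagTable, genome: dict[str, str],
               params: NovelParams | None = None,
               exclude_tags: set[str] | None = None
               ) -> tuple[list[NovelCall], pd.DataFrame]:
    """Predict novel miRNAs from the unannotated tag table.

    Overlapping mapped loci are merged; the highest-count tag represents
    each cluster.  A mature mapping to several loci is reported once, with
    every locus listed; ids (``novel_mir_N``) are assigned to accepted
    calls in descending total count.  The verdict matrix covers every
    evaluated cluster, accepted or not.
    """
    params = params or NovelParams()
    if exclude_tags:
        table = table.drop(exclude_tags)
    loci = map_unannotated(table, genome, params)
    totals = table.row_totals()
    verdict_rows = []
    by_mature: dict[str, dict] = {}

    if not loci.empty:
        for ci, cluster in enumerate(_merge_clusters(loci)):
            rep_tag = sorted(cluster["members"],
                             key=lambda m: (-int(totals[m[0]]), m[0]))[0][0]
            m_start, m_end = next((s, e) for t, s, e in cluster["members"]
                                  if t == rep_tag)
            counts_total = int(totals[rep_tag])
            contig_seq = genome[cluster["contig"]]
            region, mat = _extract_region(contig_seq,
                                          (m_start - 1, m_end - 1),
                                          cluster["strand"], params)
            ev = evaluate_locus(region, mat, counts_total, params)
            verdict_rows.append(dict(cluster=ci, contig=cluster["contig"],
                                     strand=cluster["strand"],
                                     start=m_start, end=m_end, tag=rep_tag,
                                     total_count=counts_total,
                                     energy=ev.energy, accepted=ev.accepted,
                                     **{f"crit_{c}": ev.verdicts[c]
                                        for c in CRITERIA}))
            entry = by_mature.setdefault(rep_tag, dict(best=None, loci=[]))
            entry["loci"].append((cluster["contig"], m_start, m_end,
                                  cluster["strand"]))
            if ev.accepted and (entry["best"] is None
                                or ev.energy < entry["best"][0].energy):
                # genome coordinates of the representative window
                rs = max(0, (m_start - 1) - params.flank_max)
                if cluster["strand"] == "+":
                    w_lo = rs + ev.window[0] + 1
                    w_hi = rs + ev.window[1] + 1
                else:
                    n = len(region)
                    w_lo = rs + (n - 1 - ev.window[1]) + 1
                    w_hi = rs + (n - 1 - ev.window[0]) + 1
                entry["best"] = (ev, cluster["contig"], cluster["strand"],
                                 (m_start, m_end), (w_lo, w_hi))

    accepted = [(tag, e) for tag, e in by_mature.items()
                if e["best"] is not None]
    accepted.sort(key=lambda te: (-int(totals[te[0]]), te[0]))
    calls = []
    for rank, (tag, entry) in enumerate(accepted, start=1):
        ev, contig, strand, mlocus, wlocus = entry["best"]
        star = ""
        if ev.star is not None:
            star = ev.fold.seq[ev.star[0]:ev.star[1] + 1].replace("U", "T")
        calls.append(NovelCall(
            novel_id=f"novel_mir_{rank}", mature=tag, star_seq=star,
            contig=contig, strand=strand, mature_locus=mlocus,
            precursor_locus=wlocus, energy=ev.energy, verdicts=ev.verdicts,
            counts={lib: int(table.df.loc[tag, lib])
                    for lib in table.libraries},
            accepted=True, precursor_seq=ev.fold.seq.replace("U", "T"),
            loci=entry["loci"]))
    verdicts = pd.DataFrame(verdict_rows)
    return calls, verdicts


# -------------------------------------------------------------------- export

def calls_to_frame(calls: list[NovelCall], libraries: list[str]
                   ) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = dict(novel_id=c.novel_id, mature=c.mature, star=c.star_seq,
                   contig=c.contig, strand=c.strand,
                   mature_start=c.mature_locus[0], mature_end=c.mature_locus[1],
                   precursor_start=c.precursor_locus[0],
                   precursor_end=c.precursor_locus[1], energy=c.energy,
                   n_loci=len(c.loci),
                   loci=";".join(f"{ct}:{s}-{e}({st})"
                                 for ct, s, e, st in c.loci))
        row.update({lib: c.counts.get(lib, 0) for lib in libraries})
        rows.append(row)
    return pd.DataFrame(rows)


def calls_to_gff3(calls: list[NovelCall], path: str | Path) -> None:
    rows = []
    for c in calls:
        rows.append((c.contig, "sporomir", "miRNA_primary_transcript",
                     c.precursor_locus[0], c.precursor_locus[1], ".",
                     c.strand, ".", {"ID": c.novel_id}))
        rows.append((c.contig, "sporomir", "miRNA", c.mature_locus[0],
                     c.mature_locus[1], ".", c.strand, ".",
                     {"ID": f"{c.novel_id}.mature", "Parent": c.novel_id}))
    write_gff3(path, rows)


def precursors_to_fasta(calls: list[NovelCall], path: str | Path) -> None:
    write_fasta(path, ((f"{c.novel_id} {c.contig}:{c.precursor_locus[0]}-"
                        f"{c.precursor_locus[1]}({c.strand})",
                        c.precursor_seq or c.mature)
                       for c in calls))
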