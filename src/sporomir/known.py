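"""Known-miRNA identification and quantification.

Because the focal species may have no entries of its own in the mature
catalogue, identification is cross-species: clean tags are aligned
end-to-end (ungapped, <= 2 mismatches) against all catalogue matures, one
representative per family — the member with the highest 0-mismatch
expression — forms a temporary database, and every tag is then counted
toward exactly one representative (fewest mismatches; ties broken by
lexicographically smallest id).  Representatives whose mature cannot fold
into a hairpin precursor anywhere in the genome are flagged as
pseudo-miRNAs and excluded from differential expression; matures absent
from the genome keep catalogue-only evidence and remain valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import TagTable
from .seqio import read_fasta_with_desc, revcomp


@dataclass
class MatureRef:
    """Catalogue of (mirna_id, family, mature DNA sequence 18-26 nt)."""

    records: list[tuple[str, str, str]]

    def __post_init__(self):
        ids = [r[0] for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate miRNA ids in the mature catalogue")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MatureRef":
        """Load a miRBase-style FASTA; family from ``family=`` in the
        description, else derived by stripping the species prefix and the
        trailing letter/arm suffix of the id."""
        records = []
        for rid, desc, seq in read_fasta_with_desc(path):
            family = None
            for tok in desc.split():
                if tok.startswith("family="):
                    family = tok[len("family="):]
            if family is None:
                family = derive_family(rid)
            records.append((rid, family, seq))
        return cls(records)

    def by_id(self) -> dict[str, tuple[str, str]]:
        return {rid: (fam, seq) for rid, fam, seq in self.records}


def derive_family(mirna_id: str) -> str:
    """``csn-miR1000a`` / ``ath-miR156a-5p`` -> ``miR1000`` / ``miR156``."""
    name = mirna_id.split("-", 1)[1] if "-" in mirna_id else mirna_id
    name = name.split("-")[0]
    return name.rstrip("abcdefghijklmnopqrstuvwxyz")


def _hamming_hits(tags: list[str], matures: list[tuple[str, str]],
                  max_mm: int) -> list[tuple[str, str, int]]:
    """All (tag, mirna_id, mismatches) with equal-length Hamming <= max_mm,
    vectorised per length group."""
    hits = []
    by_len: dict[int, list[int]] = {}
    for i, t in enumerate(tags):
        by_len.setdefault(len(t), []).append(i)
    for mid, mseq in matures:
        idx = by_len.get(len(mseq))
        if not idx:
            continue
        mat = np.frombuffer("".join(tags[i] for i in idx).encode(),
                            dtype=np.uint8).reshape(len(idx), len(mseq))
        ref = np.frombuffer(mseq.encode(), dtype=np.uint8)
        mm = (mat != ref).sum(axis=1)
        for k in np.flatnonzero(mm <= max_mm):
            hits.append((tags[idx[k]], mid, int(mm[k])))
    return hits


def align_tags(table: TagTable, ref: MatureRef, max_mm: int = 2
               ) -> pd.DataFrame:
    """End-to-end ungapped alignment of every tag against every mature.

    Returns all hits (tag, mirna_id, mismatches) with mismatches <= max_mm;
    sequences of unequal length never align.
    """
    matures = [(rid, seq) for rid, _fam, seq in ref.records]
    hits = _hamming_hits(table.tags, matures, max_mm)
    return pd.DataFrame(hits, columns=["tag", "mirna_id", "mismatches"])


def build_temp_db(hits: pd.DataFrame, table: TagTable, ref: MatureRef
                  ) -> pd.DataFrame:
    """One representative per family: the member with the largest total
    count of 0-mismatch tags (ties -> lexicographically smallest id).

    Representative support is based on exact hits only, keeping the
    two-phase procedure free of circularity with the final quantification.
    """
    if hits.empty:
        raise ValueError("no catalogue hits: temporary database is empty")
    info = ref.by_id()
    totals = table.row_totals()
    support: dict[str, float] = {}
    for mid in hits.mirna_id.unique():
        exact = hits[(hits.mirna_id == mid) & (hits.mismatches == 0)]
        support[mid] = float(totals.reindex(exact.tag).fillna(0).sum())
    rows = []
    fam_members: dict[str, list[str]] = {}
    for mid in hits.mirna_id.unique():
        fam_members.setdefault(info[mid][0], []).append(mid)
    for fam, members in fam_members.items():
        rep = sorted(members, key=lambda m: (-support[m], m))[0]
        rows.append(dict(family=fam, mirna_id=rep, mature_seq=info[rep][1],
                         support=support[rep]))
    return (pd.DataFrame(rows).sort_values("family")
            .reset_index(drop=True))


def quantify(table: TagTable, temp_db: pd.DataFrame, max_mm: int = 2
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum tag counts onto temporary-database representatives.

    Each tag contributes its full count to exactly one representative: the
    one with fewest mismatches, ties broken by smallest id — no tag is
    double-counted.  Returns (profiles: miRNA x library counts,
    assignment: tag -> representative)."""
    matures = list(zip(temp_db.mirna_id, temp_db.mature_seq))
    hits = _hamming_hits(table.tags, matures, max_mm)
    best: dict[str, tuple[int, str]] = {}
    for tag, mid, mm in hits:
        cur = best.get(tag)
        if cur is None or (mm, mid) < cur:
            best[tag] = (mm, mid)
    profiles = pd.DataFrame(0, index=list(temp_db.mirna_id),
                            columns=table.libraries)
    rows = []
    for tag, (mm, mid) in best.items():
        profiles.loc[mid] += table.df.loc[tag].astype(int)
        rows.append((tag, mid, mm))
    assignment = pd.DataFrame(rows, columns=["tag", "mirna_id", "mismatches"])
    return profiles, assignment


@dataclass
class PrecursorValidation:
    validated: bool
    locus: tuple[str, int, int, str] | None = None   # contig, start, end, strand


def locate_exact(seq: str, genome: dict[str, str]
                 ) -> list[tuple[str, int, int, str]]:
    """All exact occurrences of ``seq`` on both strands, 1-based inclusive."""
    loci = []
    rc = revcomp(seq)
    for contig, text in genome.items():
        for query, strand in ((seq, "+"), (rc, "-")):
            start = text.find(query)
            while start >= 0:
                loci.append((contig, start + 1, start + len(seq), strand))
                start = text.find(query, start + 1)
    return loci


def validate_precursor(profiles: pd.DataFrame, temp_db: pd.DataFrame,
                       genome: dict[str, str], novel_params=None
                       ) -> pd.DataFrame:
    """Flag pseudo-miRNAs: representatives located in the genome whose
    candidate precursor windows never fold into a single-stem hairpin with
    the mature inside one arm.

    Matures with no genomic locus keep ``validated=True`` (catalogue-only,
    cross-species evidence); located-and-foldable ones record their first
    validating locus."""
    from . import novel

    params = novel_params or novel.NovelParams()
    seq_of = dict(zip(temp_db.mirna_id, temp_db.mature_seq))
    out = profiles.copy()
    validated, loci_txt = [], []
    for mid in out.index:
        mature = seq_of[mid]
        loci = locate_exact(mature, genome)
        if not loci:
            validated.append(True)
            loci_txt.append("")
            continue
        ok_locus = None
        for contig, start, end, strand in loci:
            if novel.hairpin_context_ok(genome[contig], (start - 1, end - 1),
                                        strand, params):
                ok_locus = f"{contig}:{start}-{end}({strand})"
                break
        validated.append(ok_locus is not None)
        loci_txt.append(ok_locus or f"{loci[0][0]}:{loci[0][1]}-{loci[0][2]}"
                        f"({loci[0][3]})*unfoldable")
    out["validated"] = validated
    out["locus"] = loci_txt
    return out


def identify_known(table: TagTable, ref: MatureRef, genome: dict[str, str],
                   max_mm: int = 2, novel_params=None
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full known-miRNA stage: align, build the temporary database,
    quantify, validate precursors.

    Returns (profiles with validation columns, temp_db, tag assignment).
    """
    hits = align_tags(table, ref, max_mm)
    if hits.empty:
        empty = pd.DataFrame(columns=list(table.libraries)
                             + ["validated", "locus"])
        return empty, pd.DataFrame(), pd.DataFrame(columns=["tag", "mirna_id",
                                                            "mismatches"])
    temp_db = build_temp_db(hits, table, ref)
    profiles, assignment = quantify(table, temp_db, max_mm)
    profiles = validate_precursor(profiles, temp_db, genome, novel_params)
    return profiles, temp_db, assignment
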