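"""Removal of non-miRNA small RNAs (rRNA/tRNA/snRNA/snoRNA, repeats).

A tag is a contaminant iff it is contained end-to-end within a catalogue
sequence (either strand) with at most ``max_mm`` mismatches — a
deterministic, brute-force-verifiable replacement for BLAST screening at
toy scale.  When a tag hits several classes the label follows a fixed
priority (rRNA > tRNA > snRNA > snoRNA > repeat), then the lowest record
id, so runs are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import TagTable
from .seqio import read_fasta_with_desc, revcomp

CLASS_PRIORITY = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat")

_BASE_CODE = {c: i for i, c in enumerate("ACGTN")}


@dataclass
class ContaminantDB:
    """Catalogue of (id, class label, sequence) records."""

    records: list[tuple[str, str, str]]

    def __post_init__(self):
        for rid, cls, seq in self.records:
            if not seq or seq != seq.upper() or set(seq) - set("ACGTN"):
                raise ValueError(f"contaminant {rid}: sequence must be "
                                 "non-empty uppercase DNA")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ContaminantDB":
        """Load a FASTA whose descriptions carry ``class=<label>``."""
        records = []
        for rid, desc, seq in read_fasta_with_desc(path):
            label = "repeat"
            for tok in desc.split():
                if tok.startswith("class="):
                    label = tok[len("class="):]
            records.append((rid, label, seq))
        return cls(records)

    def ordered(self) -> list[tuple[str, str, str]]:
        rank = {c: i for i, c in enumerate(CLASS_PRIORITY)}
        return sorted(self.records,
                      key=lambda r: (rank.get(r[1], len(CLASS_PRIORITY)), r[0]))

    def __len__(self) -> int:
        return len(self.records)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _contains_with_mm(tag: str, ref: str, max_mm: int) -> bool:
    """Tag contained in ref with <= max_mm mismatches (numpy scan)."""
    n, L = len(tag), len(ref)
    if n > L:
        return False
    t = _encode(tag)
    r = _encode(ref)
    windows = np.lib.stride_tricks.sliding_window_view(r, n)
    return bool((windows != t).sum(axis=1).min() <= max_mm)


def filter_ncrna(table: TagTable, db: ContaminantDB, max_mm: int = 0
                 ) -> tuple[TagTable, pd.DataFrame]:
    """Partition the tag table into (kept, removed-with-class-labels).

    ``removed`` carries the per-library counts of each contaminant tag plus
    ``class`` and ``hit`` columns.  ``kept`` and ``removed`` are disjoint
    and their union is the input, both by unique tags and by counts.
    """
    if max_mm not in (0, 1, 2):
        raise ValueError("max_mm must be 0, 1 or 2")
    if len(db) == 0:
        warnings.warn("empty contaminant catalogue: nothing removed")
        removed = table.df.iloc[:0].copy()
        removed["class"] = []
        removed["hit"] = []
        return table, removed

    # both strands of every catalogue entry, in class-priority order
    search = []
    for rid, cls, seq in db.ordered():
        search.append((rid, cls, seq))
        search.append((rid, cls, revcomp(seq)))

    labels: dict[str, tuple[str, str]] = {}
    if max_mm == 0:
        # fast path: plain substring containment
        for tag in table.tags:
            for rid, cls, seq in search:
                if tag in seq:
                    labels[tag] = (cls, rid)
                    break
    else:
        for tag in table.tags:
            for rid, cls, seq in search:
                if _contains_with_mm(tag, seq, max_mm):
                    labels[tag] = (cls, rid)
                    break

    removed_tags = list(labels)
    kept = table.drop(removed_tags)
    removed = table.df.loc[[t for t in table.tags if t in labels]].copy()
    removed["class"] = [labels[t][0] for t in removed.index]
    removed["hit"] = [labels[t][1] for t in removed.index]
    assert len(kept) + len(removed) == len(table)
    return kept, removed
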