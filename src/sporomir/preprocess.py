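"""Raw-read cleanup and tag collapsing.

Filters are applied in a fixed, documented order so that every read is
assigned to exactly one removal class (or survives) and counts are
conserved: mean quality -> adapter locate/trim -> no-insert -> polyA ->
length window.  The surviving inserts are collapsed into a tag table with
one row per distinct sequence and one count column per library.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .seqio import FastqRecord, read_fastq

FILTER_CLASSES = ("low_quality", "no_insert", "polyA", "too_short", "too_long")


@dataclass
class CleanParams:
    adapter_seq: str = "TGGAATTCTCGGGTGCCAAGG"
    min_len: int = 18
    max_len: int = 30
    min_mean_quality: float = 20.0
    polyA_frac_threshold: float = 0.8
    min_insert_after_trim: int = 10
    adapter_mismatches: int = 1
    adapter_min_overlap: int = 12

    def validate(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if not 0 < self.polyA_frac_threshold <= 1:
            raise ValueError("polyA_frac_threshold must be in (0, 1]")
        if not self.adapter_seq:
            raise ValueError("adapter sequence required")


@dataclass
class FilterReport:
    """Per-library accounting of the cleanup; raw = clean + sum(removed)."""

    raw: int = 0
    clean: int = 0
    removed: dict = field(default_factory=lambda: {c: 0 for c in FILTER_CLASSES})

    def check(self) -> None:
        if self.raw != self.clean + sum(self.removed.values()):
            raise AssertionError("filter report does not conserve read counts")

    def to_dict(self) -> dict:
        return {"raw": self.raw, "clean": self.clean, **self.removed}


def find_adapter(seq: str, adapter: str, max_mm: int = 1,
                 min_overlap: int = 5) -> int:
    """Earliest start of the 3' adapter in ``seq`` (or -1).

    The adapter's prefix is matched at every position allowing ``max_mm``
    mismatches; at the read end the match may be partial but must span at
    least ``min_overlap`` bases (the default of 12 keeps spurious matches
    inside random inserts vanishingly rare, which in turn makes cleaning
    idempotent on already-clean tags).
    """
    n, alen = len(seq), len(adapter)
    for s in range(0, n - min_overlap + 1):
        span = min(alen, n - s)
        mm = 0
        for a, b in zip(seq[s:s + span], adapter):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return s
    return -1


def classify_read(seq: str, qual: str, params: CleanParams
                  ) -> tuple[str | None, str | None]:
    """(surviving insert, None) or (None, removal class) for one read."""
    if sum(map(ord, qual)) / len(qual) - 33 < params.min_mean_quality:
        return None, "low_quality"
    pos = find_adapter(seq, params.adapter_seq, params.adapter_mismatches,
                       params.adapter_min_overlap)
    insert = seq[:pos] if pos >= 0 else seq
    if len(insert) < params.min_insert_after_trim:
        return None, "no_insert"
    if insert.count("A") / len(insert) >= params.polyA_frac_threshold:
        return None, "polyA"
    if len(insert) < params.min_len:
        return None, "too_short"
    if len(insert) > params.max_len:
        return None, "too_long"
    return insert, None


def clean_reads(records: Iterable[FastqRecord | tuple], params: CleanParams
                ) -> tuple[Counter, FilterReport]:
    """Clean a read stream; returns (tag multiset, report).

    ``records`` may be FastqRecord objects, ``(id, seq, qual)`` tuples, or
    ``(id, seq, qual, count)`` groups of identical reads.  Classification
    is memoised per distinct (seq, qual), which makes highly duplicated
    small-RNA libraries cheap to process.
    """
    params.validate()
    report = FilterReport()
    tags: Counter = Counter()
    cache: dict[tuple[str, str], tuple[str | None, str | None]] = {}
    for rec in records:
        if isinstance(rec, FastqRecord):
            seq, qual, count = rec.seq, rec.qual, 1
        elif len(rec) == 4:
            _, seq, qual, count = rec
        else:
            _, seq, qual = rec
            count = 1
        key = (seq, qual)
        res = cache.get(key)
        if res is None:
            res = cache[key] = classify_read(seq, qual, params)
        insert, cls = res
        report.raw += count
        if insert is None:
            report.removed[cls] += count
        else:
            report.clean += count
            tags[insert] += count
    report.check()
    return tags, report


def clean_fastq(path: str | Path, params: CleanParams
                ) -> tuple[Counter, FilterReport]:
    """Clean one FASTQ file (gzip-transparent, Phred+33)."""
    return clean_reads(read_fastq(path), params)


# ------------------------------------------------------------------ TagTable

class TagTable:
    """Collapsed unique-tag count table: rows = tag sequences, columns =
    library labels (``condition-replicate``).  Row order is deterministic:
    total count descending, then lexicographic."""

    def __init__(self, df: pd.DataFrame):
        if len(df) and (df.values < 0).any():
            raise ValueError("tag counts must be non-negative")
        self.df = df

    @classmethod
    def from_counters(cls, counters: dict[str, Counter]) -> "TagTable":
        df = pd.DataFrame(counters).fillna(0).astype(int)
        df = df[[c for c in counters]]          # preserve library order
        return cls(cls._sort(df))

    @staticmethod
    def _sort(df: pd.DataFrame) -> pd.DataFrame:
        if df.empty:
            return df
        order = pd.DataFrame({"total": df.sum(axis=1), "tag": df.index})
        idx = order.sort_values(["total", "tag"],
                                ascending=[False, True]).index
        return df.loc[idx]

    # -- basic accessors ----------------------------------------------------
    @property
    def libraries(self) -> list[str]:
        return list(self.df.columns)

    @property
    def tags(self) -> list[str]:
        return list(self.df.index)

    def __len__(self) -> int:
        return len(self.df)

    def total_counts(self) -> pd.Series:
        return self.df.sum(axis=0)

    def row_totals(self) -> pd.Series:
        return self.df.sum(axis=1)

    def subset(self, tags: Iterable[str]) -> "TagTable":
        tagset = set(tags)
        keep = [t for t in self.df.index if t in tagset]
        return TagTable(self.df.loc[keep])

    def drop(self, tags: Iterable[str]) -> "TagTable":
        return TagTable(self.df.drop(index=[t for t in tags
                                            if t in self.df.index]))

    def expand(self, library: str) -> Counter:
        """Inverse of collapsing: the tag multiset of one library."""
        col = self.df[library]
        return Counter({t: int(c) for t, c in col.items() if c > 0})

    # -- I/O ----------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.df.rename_axis("tag").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TagTable":
        return cls(pd.read_csv(path, sep="\t", index_col="tag"))

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, (tag, total) in enumerate(self.row_totals().items(), 1):
                fh.write(f">tag{i}_x{int(total)}\n{tag}\n")


def collapse_tags(streams: dict[str, Counter | Iterable[str]]) -> TagTable:
    """Collapse per-library clean-tag streams into a :class:`TagTable`."""
    counters = {}
    for lib, stream in streams.items():
        counters[lib] = stream if isinstance(stream, Counter) else Counter(stream)
    return TagTable.from_counters(counters)


def clean_libraries(sources: dict[str, object], params: CleanParams
                    ) -> tuple[TagTable, dict[str, FilterReport]]:
    """Clean every library (paths or in-memory record lists) and collapse."""
    counters, reports = {}, {}
    for lib, src in sources.items():
        if isinstance(src, (str, Path)):
            counters[lib], reports[lib] = clean_fastq(src, params)
        else:
            counters[lib], reports[lib] = clean_reads(src, params)
    return collapse_tags(counters), reports


def length_distribution(table: TagTable) -> pd.DataFrame:
    """Per-length unique/total tag counts for every library.

    Returns a long-format frame (length, library, unique, total); totals
    conserve the tag-table sums.  Raises on an empty table.
    """
    if len(table) == 0:
        raise ValueError("length distribution of an empty tag table")
    df = table.df.copy()
    lengths = pd.Series([len(t) for t in df.index], index=df.index)
    rows = []
    for lib in table.libraries:
        col = df[lib]
        for length in sorted(lengths.unique()):
            mask = lengths == length
            rows.append((int(length), lib, int((col[mask] > 0).sum()),
                         int(col[mask].sum())))
    return pd.DataFrame(rows, columns=["length", "library", "unique", "total"])


def write_reports(reports: dict[str, FilterReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({lib: r.to_dict() for lib, r in reports.items()}, fh, indent=1)
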