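"""Sequence alphabet helpers and light-weight FASTA/FASTQ/GFF3 I/O.

Sequences are held internally in DNA form (ACGT, uppercase); folding and
catalogue export convert to RNA (U) at the boundary.  FASTQ reading and
writing use a minimal 4-line codec because simulated libraries run to
10^5 reads per library; FASTA parsing goes through Biopython.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (returned in DNA form)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {id: DNA-form sequence}."""
    with _open_text(path) as fh:
        return {rec.id: to_dna(str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")}


def read_fasta_with_desc(path: str | Path) -> list[tuple[str, str, str]]:
    """Read FASTA as (id, description, DNA sequence) triples."""
    with _open_text(path) as fh:
        return [
            (rec.id, rec.description, to_dna(str(rec.seq)))
            for rec in SeqIO.parse(fh, "fasta")
        ]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]],
                rna: bool = False, width: int = 70) -> None:
    """Write (header, sequence) records; header may contain a description."""
    with _open_text(path, "wt") as fh:
        for header, seq in records:
            if rna:
                seq = to_rna(seq)
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------- FASTQ

@dataclass
class FastqRecord:
    id: str
    seq: str
    qual: str


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    """Stream a (possibly gzipped) Phred+33 FASTQ file.

    Raises ``ValueError`` naming the record number on malformed input.
    """
    with _open_text(path) as fh:
        rec_no = 0
        while True:
            header = fh.readline()
            if not header:
                return
            rec_no += 1
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") \
                    or len(seq) != len(qual) or not qual:
                raise ValueError(f"malformed FASTQ record {rec_no} in {path}")
            yield FastqRecord(header[1:].split()[0].rstrip("\n"), seq, qual)


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str, int]]) -> None:
    """Write (id_prefix, seq, qual, count) groups; each group is expanded
    into `count` consecutive records `id_prefix/1 .. id_prefix/count`."""
    with _open_text(path, "wt") as fh:
        for prefix, seq, qual, count in records:
            if count <= 0:
                continue
            body = f"\n{seq}\n+\n{qual}\n"
            fh.writelines(f"@{prefix}/{i}{body}" for i in range(1, count + 1))


def mean_quality(qual: str) -> float:
    return sum(ord(c) - 33 for c in qual) / len(qual)


# ----------------------------------------------------------------------- GFF3

def write_gff3(path: str | Path, rows: Iterable[tuple]) -> None:
    """Write GFF3 rows (seqid, source, type, start, end, score, strand,
    phase, attributes-dict); coordinates are 1-based inclusive."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for seqid, source, ftype, start, end, score, strand, phase, attrs in rows:
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                f"{seqid}\t{source}\t{ftype}\t{start}\t{end}\t{score}\t{strand}\t{phase}\t{attr_s}\n"
            )
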