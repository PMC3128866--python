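"""Sequence records and byte-deterministic FASTA/FASTQ I/O.

Reads are held as :class:`SeqRecord` objects: an id, a nucleotide string
over ``{A,C,G,T,N}`` (IUPAC ambiguity codes are tolerated in called
sequences) and optional per-base Phred qualities.  Parsing goes through
Biopython; writing is done here so that output bytes are a pure function
of the records written (stable ordering, fixed line conventions).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


@dataclass
class SeqRecord:
    """A named sequence with optional per-base Phred qualities."""

    id: str
    seq: str
    quals: list[int] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.quals is not None and len(self.quals) != len(self.seq):
            raise ValueError(
                f"{self.id}: {len(self.quals)} qualities for {len(self.seq)} bases"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SeqRecord":
        quals = None if self.quals is None else self.quals[::-1]
        return SeqRecord(self.id, revcomp(self.seq), quals)


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SeqRecord]:
    with _open_text(path) as fh:
        return [SeqRecord(r.id, str(r.seq).upper()) for r in SeqIO.parse(fh, "fasta")]


def read_fastq(path: str | Path) -> list[SeqRecord]:
    with _open_text(path) as fh:
        return [
            SeqRecord(
                r.id,
                str(r.seq).upper(),
                list(r.letter_annotations["phred_quality"]),
            )
            for r in SeqIO.parse(fh, "fastq")
        ]


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            if rec.quals is None:
                raise ValueError(f"{rec.id}: FASTQ output requires qualities")
            qline = "".join(chr(q + 33) for q in rec.quals)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qline}\n")


def iter_fastq_pairs(
    path1: str | Path, path2: str | Path
) -> Iterator[tuple[SeqRecord, SeqRecord]]:
    """Iterate mate pairs from a pair of FASTQ files in lock step."""
    r1, r2 = read_fastq(path1), read_fastq(path2)
    if len(r1) != len(r2):
        raise ValueError("mate files have different read counts")
    yield from zip(r1, r2)


def fasta_string(records: Iterable[SeqRecord], width: int = 70) -> str:
    buf = io.StringIO()
    for rec in records:
        buf.write(f">{rec.id}\n")
        for i in range(0, len(rec.seq), width):
            buf.write(rec.seq[i : i + width] + "\n")
    return buf.getvalue()
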