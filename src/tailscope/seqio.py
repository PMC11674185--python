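"""FASTA/FASTQ input and output.

Reads are kept as a lightweight ``Read`` record (name, sequence, Phred
qualities).  FASTQ is Phred+33 and is written record-per-4-lines so that a
round trip is byte identical.  No quality filtering of any kind happens at
import: the pipeline deliberately keeps low-quality reads because poly(A)
stretches often base-call poorly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .refcorrect import ReferenceAmplicon


@dataclass(frozen=True)
class Read:
    """One sequencing read with per-base Phred quality scores."""

    name: str
    seq: str
    quals: tuple[int, ...]

    def __post_init__(self):
        if len(self.seq) != len(self.quals):
            raise ValueError(
                f"read {self.name!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.quals)}")


def quals_to_str(quals: Iterable[int]) -> str:
    return "".join(chr(q + 33) for q in quals)


def quals_from_str(s: str) -> tuple[int, ...]:
    return tuple(ord(c) - 33 for c in s)


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Iterate Phred+33 FASTQ records; malformed records name their index."""
    with open(path) as fh:
        index = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ValueError(f"malformed FASTQ record at index {index} in {path}")
            seq = seq.strip()
            qual = qual.strip()
            if len(seq) != len(qual):
                raise ValueError(
                    f"malformed FASTQ record at index {index} in {path}: "
                    "sequence/quality length mismatch")
            yield Read(header[1:].strip(), seq, quals_from_str(qual))
            index += 1


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.name}\n{read.seq}\n+\n{quals_to_str(read.quals)}\n")


def read_fasta(path: str | Path, gene_id: str | None = None) -> ReferenceAmplicon:
    """Load one reference record; ``gene_id`` selects from multi-record files."""
    records: dict[str, list[str]] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                current = line[1:].split()[0]
                if current in records:
                    raise ValueError(f"duplicate FASTA id {current!r} in {path}")
                records[current] = []
            elif current is not None:
                records[current].append(line.strip())
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if gene_id is None:
        if len(records) > 1:
            raise ValueError(
                f"{path} has {len(records)} records; a gene id must be given")
        gene_id = next(iter(records))
    if gene_id not in records:
        raise KeyError(f"gene id {gene_id!r} not found in {path}")
    return ReferenceAmplicon(gene_id=gene_id, sequence="".join(records[gene_id]))


def write_fasta(ref: ReferenceAmplicon, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        fh.write(f">{ref.gene_id}\n")
        for i in range(0, len(ref.sequence), width):
            fh.write(ref.sequence[i:i + width] + "\n")
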