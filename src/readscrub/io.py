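"""Shared record types and FASTA/FASTQ readers and writers.

All coordinates in this package are 0-based, half-open; strands are
recorded as ``"+"`` / ``"-"``.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator


@dataclass(frozen=True)
class Read:
    """One sequencing read: identifier, bases, and Phred+33 quality string."""

    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


class FastqFormatError(ValueError):
    """Raised for malformed FASTQ input; carries the 0-based record index."""

    def __init__(self, message: str, record_index: int):
        super().__init__(f"record {record_index}: {message}")
        self.record_index = record_index


def read_fastq(path: str | Path) -> list[Read]:
    """Read a 4-line-per-record Phred+33 FASTQ file.

    Raises :class:`FastqFormatError` on truncated records or
    sequence/quality length mismatches, naming the offending record.
    """
    reads: list[Read] = []
    index = 0
    with open(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                if len(seq) != len(qual):
                    raise FastqFormatError(
                        f"|seq|={len(seq)} != |qual|={len(qual)}", index
                    )
                reads.append(Read(id=title.split()[0], seq=seq, qual=qual))
                index += 1
        except ValueError as exc:
            if isinstance(exc, FastqFormatError):
                raise
            raise FastqFormatError(str(exc), index) from exc
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as handle:
        for read in reads:
            handle.write(f"@{read.id}\n{read.seq}\n+\n{read.qual}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an {id: sequence} mapping (order-preserving)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as handle:
        for name, seq in records.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def file_md5(path: str | Path) -> str:
    digest = hashlib.md5()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(path: str | Path, stage: str, config: dict,
                   inputs: Iterable[str | Path] = ()) -> None:
    """Write a JSON run manifest (configs, interpreter version, input checksums)."""
    manifest = {
        "stage": stage,
        "config": config,
        "python": sys.version.split()[0],
        "inputs": {str(p): file_md5(p) for p in inputs},
    }
    with open(path, "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
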