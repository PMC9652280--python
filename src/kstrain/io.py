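"""FASTA/FASTQ reading and writing (gzip-transparent), via Biopython."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_fasta", "write_fasta", "read_fastq", "write_fastq"]


def _open_text(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} dict."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTQ file (quality ignored)."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq).upper()


def write_fastq(reads: Sequence[str], path: str | Path, prefix: str = "read",
                quality: str = "I") -> None:
    """Write reads as FASTQ with a fixed quality symbol (default Q40)."""
    with _open_text(path, "wt") as fh:
        for i, read in enumerate(reads, 1):
            fh.write(f"@{prefix}_{i}\n{read}\n+\n{quality * len(read)}\n")
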