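"""Read container and FASTQ/FASTA I/O (Phred+33)."""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTNacgtn")


@dataclass(frozen=True)
class Read:
    """One sequencing read: identifier, bases, optional Phred+33 quality string."""

    read_id: str
    seq: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.seq):
            raise ValueError(
                f"read {self.read_id}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def phred(self) -> np.ndarray | None:
        """Per-base Phred scores, or None when the read carries no qualities."""
        if self.quality is None:
            return None
        return np.frombuffer(self.quality.encode("ascii"), dtype=np.uint8) - 33

    def mean_quality(self) -> float | None:
        p = self.phred()
        return None if p is None or p.size == 0 else float(p.mean())


def _to_record(read: Read) -> SeqRecord:
    rec = SeqRecord(Seq(read.seq), id=read.read_id, description="")
    if read.quality is not None:
        rec.letter_annotations["phred_quality"] = list(
            np.frombuffer(read.quality.encode("ascii"), dtype=np.uint8) - 33
        )
    return rec


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    """Write reads as FASTQ; reads without qualities get a constant Q40 string."""
    recs = []
    for r in reads:
        if r.quality is None:
            r = Read(r.read_id, r.seq, "I" * len(r.seq))
        recs.append(_to_record(r))
    return SeqIO.write(recs, str(path), "fastq")


def write_fasta(reads: Iterable[Read], path: str | Path) -> int:
    return SeqIO.write((_to_record(r) for r in reads), str(path), "fasta")


def read_fastq(path: str | Path) -> Iterator[Read]:
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield Read(rec.id, str(rec.seq), qual)


def read_fasta_reads(path: str | Path) -> Iterator[Read]:
    for rec in SeqIO.parse(str(path), "fasta"):
        yield Read(rec.id, str(rec.seq), None)
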