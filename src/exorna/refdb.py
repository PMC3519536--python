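"""Reference databases: one tier's sequences with taxon labels and
optional rRNA/tRNA feature intervals.

Tier kinds mirror the search cascade: ``miRNA``, ``transcripts`` and
``exo_miRNA`` hold stranded (sense-only) sequences; ``genome``,
``microbiome`` and ``nt`` hold double-stranded genomic sequence, so reads may
originate from — and are matched against — either strand.

On disk a database is a FASTA file plus two sidecars: a two-column TSV
mapping sequence id to taxid, and an optional BED file (0-based half-open)
of rRNA/tRNA intervals.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError, DataError

TIER_KINDS = ("miRNA", "transcripts", "genome", "microbiome", "exo_miRNA", "nt")
#: tier kinds whose sequences are genomic, i.e. searched on both strands
DOUBLE_STRANDED_KINDS = frozenset({"genome", "microbiome", "nt"})
FEATURE_KINDS = ("rRNA", "tRNA")


@dataclass(frozen=True)
class FeatureInterval:
    """An annotated structural-RNA interval, 0-based half-open."""

    kind: str  # rRNA | tRNA
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ConfigError(f"unknown feature kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ConfigError(f"bad interval [{self.start}, {self.end})")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class ReferenceDB:
    db_id: str
    kind: str
    sequences: dict[str, str]
    taxa: dict[str, int] = field(default_factory=dict)
    features: dict[str, list[FeatureInterval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in TIER_KINDS:
            raise ConfigError(f"db {self.db_id}: unknown tier kind {self.kind!r}")
        for sid in self.taxa:
            if sid not in self.sequences:
                raise ConfigError(f"db {self.db_id}: taxon label for unknown sequence {sid!r}")
        for sid, ivals in self.features.items():
            if sid not in self.sequences:
                raise ConfigError(f"db {self.db_id}: features for unknown sequence {sid!r}")
            n = len(self.sequences[sid])
            for iv in ivals:
                if iv.end > n:
                    raise ConfigError(
                        f"db {self.db_id}: interval [{iv.start}, {iv.end}) exceeds "
                        f"length {n} of {sid!r}"
                    )

    @property
    def double_stranded(self) -> bool:
        return self.kind in DOUBLE_STRANDED_KINDS

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def taxid_of(self, seq_id: str) -> int:
        try:
            return self.taxa[seq_id]
        except KeyError:
            raise DataError(f"db {self.db_id}: no taxon label for sequence {seq_id!r}") from None


def write_db(db: ReferenceDB, prefix: str | Path) -> None:
    """Write ``<prefix>.fasta``, ``<prefix>.taxa.tsv`` and, if any features,
    ``<prefix>.features.bed``."""
    prefix = Path(prefix)
    recs = [
        SeqRecord(Seq(s), id=sid, description="") for sid, s in db.sequences.items()
    ]
    SeqIO.write(recs, str(prefix.with_suffix(".fasta")), "fasta")
    with open(prefix.parent / (prefix.name + ".taxa.tsv"), "w") as fh:
        for sid, tid in db.taxa.items():
            fh.write(f"{sid}\t{tid}\n")
    if any(db.features.values()):
        with open(prefix.parent / (prefix.name + ".features.bed"), "w") as fh:
            for sid, ivals in db.features.items():
                for iv in ivals:
                    fh.write(f"{sid}\t{iv.start}\t{iv.end}\t{iv.kind}\n")


def read_db(
    db_id: str,
    kind: str,
    fasta: str | Path,
    taxa_tsv: str | Path | None = None,
    features_bed: str | Path | None = None,
) -> ReferenceDB:
    sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    taxa: dict[str, int] = {}
    if taxa_tsv is not None:
        with open(taxa_tsv) as fh:
            for line in fh:
                if not line.strip():
                    continue
                sid, tid = line.rstrip("\n").split("\t")[:2]
                taxa[sid] = int(tid)
    features: dict[str, list[FeatureInterval]] = {}
    if features_bed is not None:
        with open(features_bed) as fh:
            for line in fh:
                if not line.strip():
                    continue
                sid, start, end, kind_ = line.rstrip("\n").split("\t")[:4]
                features.setdefault(sid, []).append(
                    FeatureInterval(kind_, int(start), int(end))
                )
    return ReferenceDB(db_id, kind, sequences, taxa, features)
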