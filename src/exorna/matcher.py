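"""Exact k-mismatch (k <= 2) matching of short reads against reference tiers.

The index uses pigeonhole seeding: a read allowed up to ``m`` mismatches is
split into ``m + 1`` contiguous segments (lengths differing by at most one);
any placement with <= m mismatches must match at least one segment exactly,
so exact segment lookup generates a complete candidate set which is then
verified by full Hamming comparison.  This trades speed for auditability:
the result set provably equals a naive all-positions Hamming scan.

Only the sense strand is stored.  For double-stranded (genomic) tiers the
reverse-complemented read is additionally queried against the sense index —
a read matching the minus strand of a window is exactly its reverse
complement matching the plus strand — and such hits are reported on the
``-`` strand with reference-forward coordinates.

N (in read or reference) never matches anything, including another N.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._seq import MAX_KMER, N_CODE, encode, kmer_codes, revcomp_codes
from .errors import ConfigError
from .reads import Read
from .refdb import ReferenceDB


@dataclass(frozen=True)
class MatchHit:
    """One placement of a read: 0-based start on the reference forward strand."""

    read_id: str
    db_id: str
    seq_id: str
    start: int
    strand: str  # '+' or '-'
    mismatches: int


def segment_bounds(read_length: int, max_mismatches: int) -> list[tuple[int, int]]:
    """Partition ``read_length`` into ``max_mismatches + 1`` contiguous
    segments as (offset, length), lengths differing by at most 1."""
    n_seg = max_mismatches + 1
    if read_length < n_seg:
        raise ConfigError(
            f"read length {read_length} too short for {n_seg} non-empty segments"
        )
    base, extra = divmod(read_length, n_seg)
    bounds = []
    off = 0
    for i in range(n_seg):
        length = base + (1 if i < extra else 0)
        bounds.append((off, length))
        off += length
    return bounds


class SeedIndex:
    """Segment-seeded index of one database at one (read length, tolerance).

    Sequences are concatenated into one code array; per distinct segment
    length a sorted (key, position) table supports binary-search lookup of
    exact segment occurrences.
    """

    def __init__(self, db: ReferenceDB, read_length: int, max_mismatches: int):
        if max_mismatches not in (0, 1, 2):
            raise ConfigError(f"max_mismatches must be 0, 1 or 2, got {max_mismatches}")
        self.db = db
        self.read_length = read_length
        self.max_mismatches = max_mismatches
        self.segments = segment_bounds(read_length, max_mismatches)

        self.seq_ids: list[str] = list(db.sequences)
        lens = np.array([len(db.sequences[s]) for s in self.seq_ids], dtype=np.int64)
        self.seq_lens = lens
        self.seq_starts = np.concatenate(([0], np.cumsum(lens)))[:-1]
        self.total = int(lens.sum())
        self.codes = np.empty(self.total, dtype=np.uint8)
        for sid, gstart, n in zip(self.seq_ids, self.seq_starts, lens):
            self.codes[gstart : gstart + n] = encode(db.sequences[sid])

        # one seed table per distinct segment length: sorted keys + positions
        self._tables: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for k in sorted({length for _, length in self.segments}):
            self._tables[k] = self._build_table(k)

    def _build_table(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        keys_parts, pos_parts = [], []
        for gstart, n in zip(self.seq_starts, self.seq_lens):
            if n < k:
                continue
            keys, valid = kmer_codes(self.codes[gstart : gstart + n], k)
            idx = np.nonzero(valid)[0]
            keys_parts.append(keys[idx])
            pos_parts.append((gstart + idx).astype(np.int64))
        if not keys_parts:
            return (np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64))
        keys = np.concatenate(keys_parts)
        pos = np.concatenate(pos_parts)
        order = np.argsort(keys, kind="stable")
        return (keys[order], pos[order])

    def n_indexed_windows(self) -> int:
        """Number of distinct read-length windows reachable through the index
        (both strands for double-stranded tiers)."""
        per_strand = int(np.maximum(self.seq_lens - self.read_length + 1, 0).sum())
        return per_strand * (2 if self.db.double_stranded else 1)

    def _segment_key(self, read_codes: np.ndarray, off: int, length: int) -> np.uint64 | None:
        k_eff = min(length, MAX_KMER)
        seg = read_codes[off : off + k_eff]
        if (seg == N_CODE).any():
            return None
        key = 0
        for c in seg:
            key = (key << 2) | int(c)
        # match the table dtype exactly: a python-int needle would force a
        # whole-array cast inside searchsorted on every lookup
        return np.uint64(key)

    def _candidate_starts(self, read_codes: np.ndarray) -> np.ndarray:
        """Window starts (global coords) reachable by exact segment lookup."""
        parts = []
        for off, length in self.segments:
            key = self._segment_key(read_codes, off, length)
            if key is None:
                continue
            keys, pos = self._tables[length]
            lo = np.searchsorted(keys, key, side="left")
            hi = np.searchsorted(keys, key, side="right")
            if hi > lo:
                parts.append(pos[lo:hi] - off)
        if not parts:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(parts))

    def _verify(
        self, read_codes: np.ndarray, starts: np.ndarray, max_mismatches: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Filter candidate starts to in-bounds windows within Hamming
        tolerance; returns (starts, mismatch counts)."""
        L = self.read_length
        starts = starts[starts >= 0]
        if starts.size == 0:
            return starts, np.empty(0, dtype=np.int64)
        seq_idx = np.searchsorted(self.seq_starts, starts, side="right") - 1
        in_bounds = starts - self.seq_starts[seq_idx] + L <= self.seq_lens[seq_idx]
        starts = starts[in_bounds]
        if starts.size == 0:
            return starts, np.empty(0, dtype=np.int64)
        windows = self.codes[starts[:, None] + np.arange(L)]
        mm = (
            (windows != read_codes)
            | (windows == N_CODE)
            | (read_codes == N_CODE)
        ).sum(axis=1)
        keep = mm <= max_mismatches
        return starts[keep], mm[keep]

    def locate(self, gstart: int) -> tuple[str, int]:
        """Map a global window start to (sequence id, local start)."""
        i = int(np.searchsorted(self.seq_starts, gstart, side="right") - 1)
        return self.seq_ids[i], int(gstart - self.seq_starts[i])


def build_index(db: ReferenceDB, read_length: int, max_mismatches: int) -> SeedIndex:
    return SeedIndex(db, read_length, max_mismatches)


def find_matches(
    index: SeedIndex, read: Read, max_mismatches: int | None = None
) -> list[MatchHit]:
    """All placements of ``read`` with Hamming distance <= ``max_mismatches``.

    ``max_mismatches`` defaults to the index's tolerance and may be lowered
    (the segment seeding stays complete); it cannot exceed it.
    """
    m = index.max_mismatches if max_mismatches is None else max_mismatches
    if m > index.max_mismatches:
        raise ConfigError(
            f"index built for <= {index.max_mismatches} mismatches, requested {m}"
        )
    if len(read.seq) != index.read_length:
        raise ConfigError(
            f"read {read.read_id} has length {len(read.seq)}; index expects "
            f"{index.read_length} (dispatch reads to a per-length index)"
        )
    hits: list[MatchHit] = []
    queries = [("+", encode(read.seq))]
    if index.db.double_stranded:
        queries.append(("-", revcomp_codes(queries[0][1])))
    for strand, codes in queries:
        starts, mms = index._verify(codes, index._candidate_starts(codes), m)
        for g, mm in zip(starts, mms):
            seq_id, local = index.locate(int(g))
            hits.append(MatchHit(read.read_id, index.db.db_id, seq_id, local, strand, int(mm)))
    hits.sort(key=lambda h: (h.seq_id, h.start, h.strand))
    return hits


def hamming_scan(
    db: ReferenceDB, read: Read, max_mismatches: int
) -> list[MatchHit]:
    """Naive all-positions Hamming scan — the reference oracle the seeded
    index must reproduce exactly.  Quadratic; small inputs only."""
    L = len(read.seq)
    rc = revcomp_codes(encode(read.seq))
    fw = encode(read.seq)
    hits = []
    for seq_id, seq in db.sequences.items():
        ref = encode(seq)
        strands = [("+", fw), ("-", rc)] if db.double_stranded else [("+", fw)]
        for start in range(len(seq) - L + 1):
            window = ref[start : start + L]
            for strand, q in strands:
                mm = int(
                    ((window != q) | (window == N_CODE) | (q == N_CODE)).sum()
                )
                if mm <= max_mismatches:
                    hits.append(
                        MatchHit(read.read_id, db.db_id, seq_id, start, strand, mm)
                    )
    hits.sort(key=lambda h: (h.seq_id, h.start, h.strand))
    return hits


def hits_to_tsv(hits: Sequence[MatchHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tdb_id\tseq_id\tstart\tstrand\tmismatches\n")
        for h in hits:
            fh.write(
                f"{h.read_id}\t{h.db_id}\t{h.seq_id}\t{h.start}\t{h.strand}\t{h.mismatches}\n"
            )


def hits_to_sam(
    hits: Sequence[MatchHit], db: ReferenceDB, read_seqs: dict[str, str], path
) -> None:
    """Minimal SAM export (flag 0/16, NM tag) for interoperability."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for sid, seq in db.sequences.items():
            fh.write(f"@SQ\tSN:{sid}\tLN:{len(seq)}\n")
        for h in hits:
            seq = read_seqs[h.read_id]
            flag = 0 if h.strand == "+" else 16
            fh.write(
                f"{h.read_id}\t{flag}\t{h.seq_id}\t{h.start + 1}\t255\t"
                f"{len(seq)}M\t*\t0\t0\t{seq}\t*\tNM:i:{h.mismatches}\n"
            )
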