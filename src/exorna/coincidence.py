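"""Expected rate of chance matches of random reads in a foreign database.

This formalizes the negative-control argument: a read of length L allowed m
mismatches against a database exposing N searchable positions has a
per-position match probability

    p = sum_{i=0..m} C(L, i) q^i (1 - q)^(L - i),

where q is the per-base mismatch probability under the background base
composition (uniform case q = 3/4, so the exact-match term is (1/4)^L).
Treating positions as independent, the probability that the read matches
anywhere is 1 - (1 - p)^N, with the Poisson approximation 1 - exp(-N p)
agreeing to < 1% relative error whenever N p < 0.01.  Overlapping windows
are weakly dependent, so independence is an (accurate, standard) occupancy
approximation; the Monte-Carlo routine below checks it empirically.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._seq import decode
from .errors import ConfigError, DataError
from .matcher import build_index, find_matches
from .reads import Read
from .refdb import ReferenceDB

UNIFORM = (0.25, 0.25, 0.25, 0.25)


@dataclass
class CoincidenceParams:
    read_length: int
    max_mismatches: int
    n_positions: int  # sum over db of strands x (seq length - L + 1)
    composition: tuple[float, float, float, float] = UNIFORM

    def __post_init__(self) -> None:
        if self.max_mismatches > self.read_length:
            raise ConfigError(
                f"mismatch allowance {self.max_mismatches} exceeds read length {self.read_length}"
            )
        if self.max_mismatches < 0 or self.read_length < 1:
            raise ConfigError("read length must be >= 1 and allowance >= 0")
        if self.n_positions < 0:
            raise ConfigError("searchable positions must be >= 0")
        comp = np.asarray(self.composition, dtype=float)
        if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1.0) > 1e-12:
            raise ConfigError("composition must be 4 probabilities summing to 1")

    @property
    def per_base_mismatch(self) -> float:
        """q: probability two independent draws from the composition differ."""
        comp = np.asarray(self.composition)
        return float(1.0 - (comp**2).sum())


def searchable_positions(db: ReferenceDB, read_length: int) -> int:
    per_strand = sum(
        max(len(s) - read_length + 1, 0) for s in db.sequences.values()
    )
    return per_strand * (2 if db.double_stranded else 1)


def empirical_composition(db: ReferenceDB) -> tuple[float, float, float, float]:
    counts = np.zeros(4)
    for seq in db.sequences.values():
        for i, b in enumerate("ACGT"):
            counts[i] += seq.count(b)
    if counts.sum() == 0:
        return UNIFORM
    return tuple(counts / counts.sum())


def per_position_match_probability(params: CoincidenceParams) -> float:
    """p: probability one random read matches one fixed position within the
    allowance (Binomial(L, q) lower tail on mismatches)."""
    return float(
        stats.binom.cdf(params.max_mismatches, params.read_length, params.per_base_mismatch)
    )


def expected_coincidental_fraction(
    params: CoincidenceParams, poisson: bool = False
) -> float:
    """Probability a random read matches >= 1 of the N searchable positions.

    Exact (under position independence): 1 - (1 - p)^N.  With
    ``poisson=True`` returns the 1 - exp(-N p) approximation instead.
    """
    p = per_position_match_probability(params)
    n = params.n_positions
    if poisson:
        return float(-np.expm1(-n * p))
    if p >= 1.0:
        return 1.0 if n >= 1 else 0.0
    return float(-np.expm1(n * np.log1p(-p)))


def simulate_coincidence(
    db: ReferenceDB,
    n_reads: int,
    read_length: int,
    max_mismatches: int,
    seed: int,
    composition: tuple[float, float, float, float] | None = None,
) -> float:
    """Empirical fraction of random background reads with >= 1 hit in ``db``
    at <= ``max_mismatches``, using the production matcher."""
    if db.n_sequences == 0:
        return 0.0
    if read_length > max(len(s) for s in db.sequences.values()):
        raise DataError(f"read length {read_length} exceeds every database sequence")
    comp = empirical_composition(db) if composition is None else composition
    rng = np.random.default_rng(seed)
    index = build_index(db, read_length, max_mismatches)
    codes = rng.choice(4, size=(n_reads, read_length), p=np.asarray(comp)).astype(np.uint8)
    flat = decode(codes.ravel())
    n_hit = 0
    for i in range(n_reads):
        read = Read(f"bg{i}", flat[i * read_length : (i + 1) * read_length])
        if find_matches(index, read, max_mismatches):
            n_hit += 1
    return n_hit / n_reads
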