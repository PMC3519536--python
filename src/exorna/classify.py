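"""The tiered "map and remove" cascade.

Reads are screened against an ordered list of reference tiers; a read with at
least one valid hit in the current tier is assigned that tier's category and
removed from the stream, so it is never tested against later tiers.  Host
tiers come first (miRNA, transcripts, genome), then the exogenous tiers
(microbiome, foreign miRNA, the nt collection).  The mismatch allowance of
the strategy-controlled host tiers (transcripts, genome) is the Strategy
value (0, 1 or 2); miRNA tiers and all exogenous tiers always require exact
matches because conserved/similar sequences make looser matching unreliable.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, UndefinedFractionError
from .matcher import MatchHit, SeedIndex, build_index, find_matches
from .reads import Read
from .refdb import ReferenceDB

UNMAPPED = "unmapped"

POLICY_FIXED0 = "fixed0"
POLICY_STRATEGY = "strategy"

VALID_STRATEGIES = (0, 1, 2)


@dataclass(frozen=True)
class Tier:
    db_id: str
    category: str
    policy: str  # POLICY_FIXED0 | POLICY_STRATEGY

    def __post_init__(self) -> None:
        if self.policy not in (POLICY_FIXED0, POLICY_STRATEGY):
            raise ConfigError(f"tier {self.category!r}: unknown policy {self.policy!r}")

    def allowance(self, strategy: int) -> int:
        return strategy if self.policy == POLICY_STRATEGY else 0


@dataclass
class TierSpec:
    """Ordered tier list; category labels must be unique and must not shadow
    the reserved "unmapped" category."""

    tiers: list[Tier]

    def __post_init__(self) -> None:
        labels = [t.category for t in self.tiers]
        if len(set(labels)) != len(labels):
            raise ConfigError(f"duplicate tier category labels: {labels}")
        if UNMAPPED in labels:
            raise ConfigError(f'"{UNMAPPED}" is reserved for unassigned reads')

    def __iter__(self):
        return iter(self.tiers)

    def __len__(self) -> int:
        return len(self.tiers)

    @classmethod
    def plasma_default(
        cls,
        host_mirna: str = "host_mirna",
        host_transcripts: str = "host_transcripts",
        host_genome: str = "host_genome",
        microbiome: str = "microbiome",
        exo_mirna: str = "exo_mirna",
        nt: str = "nt",
    ) -> "TierSpec":
        """The canonical six-tier plasma cascade in its fixed search order."""
        return cls(
            [
                Tier(host_mirna, "Endogenous miRNA", POLICY_FIXED0),
                Tier(host_transcripts, "Human transcripts", POLICY_STRATEGY),
                Tier(host_genome, "Human genome", POLICY_STRATEGY),
                Tier(microbiome, "Microbiome", POLICY_FIXED0),
                Tier(exo_mirna, "Exogenous miRNA", POLICY_FIXED0),
                Tier(nt, "Other species (nt)", POLICY_FIXED0),
            ]
        )


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    length: int
    category: str
    tier_index: int  # -1 for unmapped
    hits: tuple[MatchHit, ...]


@dataclass
class ClassificationTable:
    """The pipeline's central ledger: one final category per read."""

    strategy: int
    tier_order: list[str]  # category labels in search order
    assignments: dict[str, ReadAssignment] = field(default_factory=dict)

    @property
    def n_reads(self) -> int:
        return len(self.assignments)

    def category_counts(self) -> dict[str, int]:
        """Counts for every tier category (zeros included) plus unmapped."""
        counts = Counter(a.category for a in self.assignments.values())
        return {c: counts.get(c, 0) for c in [*self.tier_order, UNMAPPED]}

    def reads_in(self, category: str) -> list[ReadAssignment]:
        return [a for a in self.assignments.values() if a.category == category]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "read_id": a.read_id,
                "length": a.length,
                "category": a.category,
                "tier_index": a.tier_index,
                "n_hits": len(a.hits),
            }
            for a in self.assignments.values()
        ]
        return pd.DataFrame(
            rows, columns=["read_id", "length", "category", "tier_index", "n_hits"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class IndexCache:
    """Lazy per-(db, read length, tolerance) index store, reusable across
    strategies and cascade runs."""

    def __init__(self, dbs: Mapping[str, ReferenceDB]):
        self.dbs = dict(dbs)
        self._cache: dict[tuple[str, int, int], SeedIndex] = {}

    def get(self, db_id: str, read_length: int, max_mismatches: int) -> SeedIndex:
        key = (db_id, read_length, max_mismatches)
        if key not in self._cache:
            self._cache[key] = build_index(self.dbs[db_id], read_length, max_mismatches)
        return self._cache[key]


def run_map_and_remove(
    reads: Sequence[Read],
    dbs: Mapping[str, ReferenceDB] | IndexCache,
    tiers: TierSpec,
    strategy: int,
) -> ClassificationTable:
    """Classify reads through the cascade at the given Strategy.

    Tiers are processed in order; each read is assigned to the first tier
    with >= 1 hit (all hits at that tier are retained for taxonomy) and
    survivors of the last tier are "unmapped".
    """
    if strategy not in VALID_STRATEGIES:
        raise ConfigError(f"strategy must be one of {VALID_STRATEGIES}, got {strategy}")
    cache = dbs if isinstance(dbs, IndexCache) else IndexCache(dbs)
    for tier in tiers:
        if tier.db_id not in cache.dbs:
            raise ConfigError(f"tier {tier.category!r}: unknown database {tier.db_id!r}")
        if cache.dbs[tier.db_id].n_sequences == 0:
            raise ConfigError(f"tier {tier.category!r}: database {tier.db_id!r} is empty")
    ids = [r.read_id for r in reads]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate read ids in input")

    table = ClassificationTable(strategy=strategy, tier_order=[t.category for t in tiers])
    surviving = list(reads)
    for tier_index, tier in enumerate(tiers):
        m = tier.allowance(strategy)
        next_round: list[Read] = []
        for read in surviving:
            if len(read.seq) < m + 1:
                next_round.append(read)  # too short to index at this tolerance
                continue
            index = cache.get(tier.db_id, len(read.seq), m)
            hits = find_matches(index, read, m)
            if hits:
                table.assignments[read.read_id] = ReadAssignment(
                    read.read_id, len(read.seq), tier.category, tier_index, tuple(hits)
                )
            else:
                next_round.append(read)
        surviving = next_round
    for read in surviving:
        table.assignments[read.read_id] = ReadAssignment(
            read.read_id, len(read.seq), UNMAPPED, -1, ()
        )
    return table


def category_fractions(table: ClassificationTable) -> dict[str, float]:
    """Per-category percentages over processed reads; sums to 100 within
    floating rounding."""
    if table.n_reads == 0:
        raise UndefinedFractionError("category fractions undefined for zero processed reads")
    counts = table.category_counts()
    return {c: 100.0 * n / table.n_reads for c, n in counts.items()}


def strategy_sweep(
    reads: Sequence[Read],
    dbs: Mapping[str, ReferenceDB] | IndexCache,
    tiers: TierSpec,
    strategies: Iterable[int] = VALID_STRATEGIES,
) -> dict[int, ClassificationTable]:
    """Run the cascade at several strategies on the identical processed-read
    set, sharing indexes where tolerances coincide."""
    cache = dbs if isinstance(dbs, IndexCache) else IndexCache(dbs)
    return {s: run_map_and_remove(reads, cache, tiers, s) for s in strategies}
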