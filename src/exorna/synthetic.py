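"""Synthetic communities and Illumina-like short-read simulation.

This module generates the study conditions the pipeline assumes: a
host-dominant mixture of reference tiers; shared, highly conserved
structural-RNA genes copied across taxa at a stated divergence (emulating
rRNA/tRNA cross-species similarity and the misassignment it causes); unequal
food-species abundances; and per-cycle substitution errors on fixed-length
reads.  Ground truth (source sequence, taxon, interval, strand, error
positions) is emitted for every read, enabling exact accuracy scoring.

The error model is substitution-only: classification tolerances are pure
mismatch counts, so indels would never be scored.  Reads are drawn from the
sense strand of transcript-type databases and from either strand (p = 0.5)
of genome-type databases; start positions are uniform over eligible
positions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from ._seq import decode, encode
from .errors import ConfigError, DataError
from .reads import Read
from .refdb import FEATURE_KINDS, ReferenceDB, FeatureInterval, TIER_KINDS
from .taxonomy import TaxNode, TaxonomyTree

_RANKS = ("kingdom", "phylum", "genus", "species")


@dataclass
class ErrorProfile:
    """Per-cycle substitution model for fixed-length reads.

    ``per_cycle_sub_rate[c]`` is the probability that cycle ``c`` reads the
    wrong base (uniform over the three alternatives); ``quality_model[c]`` is
    the mean Phred score written at that cycle.  Substitution is governed
    solely by the rates — qualities are cosmetic output.
    """

    read_length: int
    per_cycle_sub_rate: np.ndarray
    quality_model: np.ndarray

    def __post_init__(self) -> None:
        self.per_cycle_sub_rate = np.asarray(self.per_cycle_sub_rate, dtype=float)
        self.quality_model = np.asarray(self.quality_model, dtype=float)
        if self.read_length < 1:
            raise ConfigError("read_length must be positive")
        if self.per_cycle_sub_rate.shape != (self.read_length,):
            raise ConfigError("per_cycle_sub_rate must have one entry per cycle")
        if self.quality_model.shape != (self.read_length,):
            raise ConfigError("quality_model must have one entry per cycle")
        if ((self.per_cycle_sub_rate < 0) | (self.per_cycle_sub_rate > 1)).any():
            raise ConfigError("substitution rates must lie in [0, 1]")

    @classmethod
    def illumina_like(cls, read_length: int = 23, mean_rate: float = 0.005) -> "ErrorProfile":
        """Illumina-style profile: error rate ramps up along the read (3' end
        worst), averaging ``mean_rate``; qualities mirror the rates."""
        if not 0 <= mean_rate <= 1:
            raise ConfigError("mean_rate must lie in [0, 1]")
        ramp = np.linspace(0.4, 1.6, read_length)
        rates = np.clip(mean_rate * ramp, 0.0, 1.0)
        with np.errstate(divide="ignore"):
            quals = np.where(rates > 0, -10.0 * np.log10(np.maximum(rates, 1e-9)), 40.0)
        return cls(read_length, rates, np.clip(quals, 2, 40))

    @classmethod
    def error_free(cls, read_length: int = 23) -> "ErrorProfile":
        return cls(read_length, np.zeros(read_length), np.full(read_length, 40.0))

    def quality_string(self) -> str:
        return "".join(chr(int(round(q)) + 33) for q in self.quality_model)


@dataclass(frozen=True)
class MixtureComponent:
    db_id: str
    taxid: int
    weight: float


@dataclass
class MixtureSpec:
    """What to simulate: weighted taxon components, total read count, seed.
    Weights are normalized internally to proportions."""

    components: list[MixtureComponent]
    n_reads: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ConfigError("n_reads must be positive")
        if not self.components:
            raise ConfigError("mixture needs at least one component")
        if any(c.weight < 0 for c in self.components):
            raise ConfigError("component weights must be non-negative")
        if sum(c.weight for c in self.components) <= 0:
            raise ConfigError("component weights must sum to a positive value")

    @property
    def proportions(self) -> np.ndarray:
        w = np.array([c.weight for c in self.components], dtype=float)
        return w / w.sum()


@dataclass(frozen=True)
class TruthRecord:
    """Simulator ground truth for one read; interval is 0-based half-open on
    the source sequence's forward strand."""

    read_id: str
    db_id: str
    seq_id: str
    taxid: int
    start: int
    end: int
    strand: str
    error_positions: tuple[int, ...]  # cycle indices, strictly increasing


# ---------------------------------------------------------------------------
# community configuration


@dataclass
class TaxonConfig:
    name: str
    n_sequences: int
    length_range: tuple[int, int]
    gc: float = 0.5
    genus: str | None = None
    phylum: str = "SynPhylum"
    kingdom: str = "SynKingdom"

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if self.n_sequences < 1:
            raise ConfigError(f"taxon {self.name}: needs at least one sequence")
        if lo < 1 or hi < lo:
            raise ConfigError(f"taxon {self.name}: invalid length range {self.length_range}")
        if not 0.0 <= self.gc <= 1.0:
            raise ConfigError(f"taxon {self.name}: GC content {self.gc} outside [0, 1]")


@dataclass
class ConservedGeneConfig:
    """A structural-RNA gene copied into several taxa with per-copy divergence."""

    name: str
    kind: str  # rRNA | tRNA
    length: int
    divergence: float
    members: list[str]  # taxon names within the same database

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ConfigError(f"conserved gene {self.name}: kind must be one of {FEATURE_KINDS}")
        if self.length < 1:
            raise ConfigError(f"conserved gene {self.name}: zero-length request")
        if not 0.0 <= self.divergence <= 1.0:
            raise ConfigError(f"conserved gene {self.name}: divergence outside [0, 1]")
        if len(self.members) < 1:
            raise ConfigError(f"conserved gene {self.name}: needs at least one member taxon")


@dataclass
class DatabaseConfig:
    db_id: str
    kind: str
    taxa: list[TaxonConfig]
    conserved_genes: list[ConservedGeneConfig] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in TIER_KINDS:
            raise ConfigError(f"db {self.db_id}: unknown tier kind {self.kind!r}")
        names = {t.name for t in self.taxa}
        for g in self.conserved_genes:
            missing = set(g.members) - names
            if missing:
                raise ConfigError(
                    f"db {self.db_id}: conserved gene {g.name} references unknown taxa {sorted(missing)}"
                )


@dataclass
class CommunityConfig:
    databases: list[DatabaseConfig]
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [d.db_id for d in self.databases]
        if len(set(ids)) != len(ids):
            raise ConfigError(f"duplicate database ids: {ids}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CommunityConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        dbs = []
        for d in raw["databases"]:
            taxa = [
                TaxonConfig(
                    name=t["name"],
                    n_sequences=int(t["n_sequences"]),
                    length_range=tuple(t["length_range"]),
                    gc=float(t.get("gc", 0.5)),
                    genus=t.get("genus"),
                    phylum=t.get("phylum", "SynPhylum"),
                    kingdom=t.get("kingdom", "SynKingdom"),
                )
                for t in d["taxa"]
            ]
            genes = [
                ConservedGeneConfig(
                    name=g["name"],
                    kind=g["kind"],
                    length=int(g["length"]),
                    divergence=float(g["divergence"]),
                    members=list(g["members"]),
                )
                for g in d.get("conserved_genes", [])
            ]
            dbs.append(DatabaseConfig(d["db_id"], d["kind"], taxa, genes))
        return cls(dbs, seed=int(raw.get("seed", 0)))


# ---------------------------------------------------------------------------
# generation


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]
    return decode(rng.choice(4, size=length, p=probs).astype(np.uint8))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    codes = encode(seq).copy()
    mask = rng.random(codes.size) < rate
    if mask.any():
        shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
        codes[mask] = (codes[mask] + shift) % 4
    return decode(codes)


def generate_reference_set(
    config: CommunityConfig,
) -> tuple[dict[str, ReferenceDB], TaxonomyTree]:
    """Build all tier databases plus the taxonomy table.

    Deterministic for a fixed ``config.seed``; every sequence carries a taxon
    label resolvable in the emitted taxonomy; conserved-gene copies become
    annotated rRNA/tRNA feature intervals.
    """
    rng = np.random.default_rng(config.seed)

    # taxonomy: root -> kingdom -> phylum -> genus -> species
    nodes = [TaxNode(1, 1, "root", "root")]
    next_id = 2
    by_key: dict[tuple, int] = {}

    def node_for(rank: str, name: str, parent: int) -> int:
        nonlocal next_id
        key = (rank, name, parent)
        if key not in by_key:
            by_key[key] = next_id
            nodes.append(TaxNode(next_id, parent, rank, name))
            next_id += 1
        return by_key[key]

    species_taxid: dict[str, int] = {}
    for dbc in config.databases:
        for t in dbc.taxa:
            kid = node_for("kingdom", t.kingdom, 1)
            pid = node_for("phylum", t.phylum, kid)
            gid = node_for("genus", t.genus or f"{t.name}_genus", pid)
            sid = node_for("species", t.name, gid)
            if t.name in species_taxid and species_taxid[t.name] != sid:
                raise ConfigError(f"taxon name {t.name!r} maps to two lineages")
            species_taxid[t.name] = sid
    tree = TaxonomyTree(nodes)

    dbs: dict[str, ReferenceDB] = {}
    for dbc in config.databases:
        sequences: dict[str, str] = {}
        taxa: dict[str, int] = {}
        features: dict[str, list[FeatureInterval]] = {}
        first_seq_of: dict[str, str] = {}
        for t in dbc.taxa:
            lo, hi = t.length_range
            for i in range(t.n_sequences):
                sid = f"{t.name}.{i}"
                length = int(rng.integers(lo, hi + 1))
                sequences[sid] = _random_sequence(rng, length, t.gc)
                taxa[sid] = species_taxid[t.name]
                first_seq_of.setdefault(t.name, sid)
        for gene in dbc.conserved_genes:
            master = _random_sequence(rng, gene.length, 0.5)
            for taxon_name in gene.members:
                target = first_seq_of[taxon_name]
                host = sequences[target]
                if len(host) < gene.length:
                    raise ConfigError(
                        f"db {dbc.db_id}: sequence {target!r} ({len(host)} nt) too short "
                        f"for conserved gene {gene.name} ({gene.length} nt)"
                    )
                copy = _mutate(rng, master, gene.divergence)
                pos = int(rng.integers(0, len(host) - gene.length + 1))
                sequences[target] = host[:pos] + copy + host[pos + gene.length :]
                features.setdefault(target, []).append(
                    FeatureInterval(gene.kind, pos, pos + gene.length)
                )
        dbs[dbc.db_id] = ReferenceDB(dbc.db_id, dbc.kind, sequences, taxa, features)
    return dbs, tree


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    dbs: Mapping[str, ReferenceDB],
    mixture: MixtureSpec,
    profile: ErrorProfile,
    read_prefix: str = "read",
) -> tuple[list[Read], list[TruthRecord]]:
    """Draw reads from the mixture with per-cycle substitution errors.

    Component read counts follow a multinomial over the normalized weights;
    source positions are uniform over eligible windows; the substituted base
    is uniform over the three alternatives.  Reproducible for a fixed
    ``mixture.seed``; truth records exactly describe each read.
    """
    rng = np.random.default_rng(mixture.seed)
    L = profile.read_length
    counts = rng.multinomial(mixture.n_reads, mixture.proportions)
    qual = profile.quality_string()

    reads: list[Read] = []
    truths: list[TruthRecord] = []
    serial = 0
    for comp, n_comp in zip(mixture.components, counts):
        if n_comp == 0:
            continue
        if comp.db_id not in dbs:
            raise DataError(f"mixture references unknown database {comp.db_id!r}")
        db = dbs[comp.db_id]
        pool = [
            (sid, seq)
            for sid, seq in db.sequences.items()
            if db.taxa.get(sid) == comp.taxid and len(seq) >= L
        ]
        if not pool:
            raise DataError(
                f"mixture component (db={comp.db_id}, taxid={comp.taxid}) has an "
                f"empty source pool for read length {L}"
            )
        eligible = np.array([len(seq) - L + 1 for _, seq in pool], dtype=np.int64)
        cum = np.concatenate(([0], np.cumsum(eligible)))
        draws = rng.integers(0, cum[-1], size=n_comp)
        seq_idx = np.searchsorted(cum, draws, side="right") - 1
        offsets = draws - cum[seq_idx]
        if db.double_stranded:
            strands = np.where(rng.random(n_comp) < 0.5, "+", "-")
        else:
            strands = np.full(n_comp, "+")

        enc_cache = [encode(seq) for _, seq in pool]
        mat = np.empty((n_comp, L), dtype=np.uint8)
        for i in range(n_comp):
            window = enc_cache[seq_idx[i]][offsets[i] : offsets[i] + L]
            if strands[i] == "-":
                w = (3 - window[::-1]).astype(np.uint8)
                w[window[::-1] == 4] = 4
                mat[i] = w
            else:
                mat[i] = window

        err_mask = rng.random((n_comp, L)) < profile.per_cycle_sub_rate[None, :]
        err_mask &= mat < 4  # never substitute an N placeholder
        n_err = int(err_mask.sum())
        if n_err:
            shift = rng.integers(1, 4, size=n_err, dtype=np.uint8)
            mat[err_mask] = (mat[err_mask] + shift) % 4
        err_by_row: dict[int, list[int]] = {}
        for i, j in np.argwhere(err_mask):
            err_by_row.setdefault(int(i), []).append(int(j))

        flat = decode(mat.ravel())
        for i in range(n_comp):
            rid = f"{read_prefix}{serial:08d}"
            serial += 1
            sid = pool[seq_idx[i]][0]
            start = int(offsets[i])
            reads.append(Read(rid, flat[i * L : (i + 1) * L], qual))
            truths.append(
                TruthRecord(
                    rid,
                    comp.db_id,
                    sid,
                    comp.taxid,
                    start,
                    start + L,
                    str(strands[i]),
                    tuple(err_by_row.get(i, ())),
                )
            )
    return reads, truths


def truth_to_tsv(truths: Sequence[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tdb_id\tseq_id\ttaxid\tstart\tend\tstrand\terror_positions\n")
        for t in truths:
            errs = ",".join(map(str, t.error_positions))
            fh.write(
                f"{t.read_id}\t{t.db_id}\t{t.seq_id}\t{t.taxid}\t{t.start}\t{t.end}\t"
                f"{t.strand}\t{errs}\n"
            )
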