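"""Taxonomic resolution of multi-hit reads and rank rollups.

The tree is a simplified NCBI-style node table (taxid, parent taxid, rank,
name).  Reads with several equally good placements are resolved by
best-hit-then-LCA: hits are first filtered to the minimal mismatch count and
the surviving taxa are collapsed to their lowest common ancestor.  A read is
flagged as structural RNA when any surviving hit overlaps an annotated
rRNA/tRNA interval by at least one base; masking such reads and re-rolling
up reproduces the "with vs without structural RNA" comparison that guards
against conservation-driven cross-species misassignment.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, DataError
from .matcher import MatchHit
from .refdb import ReferenceDB

UNRANKED = "unranked"


@dataclass(frozen=True)
class TaxNode:
    taxid: int
    parent: int
    rank: str
    name: str


class TaxonomyTree:
    """taxid -> (parent, rank, name) with a self-parented root."""

    def __init__(self, nodes: Iterable[TaxNode]):
        self.nodes: dict[int, TaxNode] = {n.taxid: n for n in nodes}
        roots = [n.taxid for n in self.nodes.values() if n.parent == n.taxid]
        if len(roots) != 1:
            raise ConfigError(f"taxonomy must have exactly one self-parented root, found {roots}")
        self.root = roots[0]
        for n in self.nodes.values():
            if n.parent not in self.nodes:
                raise ConfigError(f"taxid {n.taxid} has unknown parent {n.parent}")
        # reject cycles / chains that never reach the root
        for tid in self.nodes:
            self.lineage(tid)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def name(self, taxid: int) -> str:
        return self.nodes[taxid].name

    def rank(self, taxid: int) -> str:
        return self.nodes[taxid].rank

    def lineage(self, taxid: int) -> list[int]:
        """Path root -> ... -> taxid."""
        if taxid not in self.nodes:
            raise DataError(f"unknown taxid {taxid}")
        path = [taxid]
        seen = {taxid}
        while path[-1] != self.root:
            parent = self.nodes[path[-1]].parent
            if parent in seen:
                raise ConfigError(f"taxonomy cycle at taxid {parent}")
            path.append(parent)
            seen.add(parent)
        return path[::-1]

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        for tid in self.lineage(taxid):
            if self.nodes[tid].rank == rank:
                return tid
        return None

    def lca(self, taxids: Sequence[int]) -> int:
        if not taxids:
            raise DataError("LCA of an empty taxon set")
        paths = [self.lineage(t) for t in set(taxids)]
        shortest = min(len(p) for p in paths)
        lca = self.root
        for i in range(shortest):
            tids = {p[i] for p in paths}
            if len(tids) != 1:
                break
            lca = tids.pop()
        return lca

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("taxid\tparent_taxid\trank\tname\n")
            for n in sorted(self.nodes.values(), key=lambda n: n.taxid):
                fh.write(f"{n.taxid}\t{n.parent}\t{n.rank}\t{n.name}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTree":
        nodes = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("taxid"):
                raise DataError(f"{path}: expected a 'taxid<TAB>parent_taxid...' header")
            for line in fh:
                if not line.strip():
                    continue
                tid, parent, rank, name = line.rstrip("\n").split("\t")[:4]
                nodes.append(TaxNode(int(tid), int(parent), rank, name))
        return cls(nodes)


@dataclass(frozen=True)
class TaxonAssignment:
    """Resolved taxon for one read."""

    read_id: str
    taxid: int
    level: str  # rank of the assigned node ("species" or the LCA's rank)
    structural_rna: bool


def assign_taxon(
    hits: Sequence[MatchHit],
    db: ReferenceDB,
    tree: TaxonomyTree,
    read_length: int,
) -> TaxonAssignment:
    """Resolve one read's hits (all within one tier's database) to a taxon.

    Hits are filtered to the minimal mismatch count; if all survivors agree on
    one taxon that taxon is assigned at its own rank, otherwise the LCA of the
    surviving taxa.  ``structural_rna`` is True iff any surviving hit overlaps
    an annotated rRNA/tRNA feature.
    """
    if not hits:
        raise DataError("assign_taxon requires at least one hit")
    if any(h.db_id != db.db_id for h in hits):
        raise DataError("assign_taxon hits must all come from one tier's database")
    best = min(h.mismatches for h in hits)
    survivors = [h for h in hits if h.mismatches == best]
    taxids = set()
    for h in survivors:
        tid = db.taxid_of(h.seq_id)
        if tid not in tree:
            raise DataError(f"sequence {h.seq_id!r} labelled with unknown taxid {tid}")
        taxids.add(tid)
    assigned = taxids.pop() if len(taxids) == 1 else tree.lca(sorted(taxids))
    flag = any(
        iv.overlaps(h.start, h.start + read_length)
        for h in survivors
        for iv in db.features.get(h.seq_id, ())
    )
    return TaxonAssignment(survivors[0].read_id, assigned, tree.rank(assigned), flag)


def rollup(
    assignments: Iterable[TaxonAssignment],
    tree: TaxonomyTree,
    rank: str,
) -> dict[str, int]:
    """Counts per taxon name at ``rank``; assignments whose lineage lacks the
    rank are pooled under ``"unranked"``.  Totals are conserved."""
    counts: Counter[str] = Counter()
    for a in assignments:
        anc = tree.ancestor_at_rank(a.taxid, rank)
        counts[UNRANKED if anc is None else tree.name(anc)] += 1
    return dict(counts)


def rollup_mean(
    per_sample: Mapping[str, Sequence[TaxonAssignment]],
    tree: TaxonomyTree,
    rank: str,
) -> pd.Series:
    """Unweighted arithmetic mean of per-sample rollup counts (plasma figures
    report the average over all samples)."""
    frames = {
        sample: pd.Series(rollup(assignments, tree, rank), dtype=float)
        for sample, assignments in per_sample.items()
    }
    table = pd.DataFrame(frames).fillna(0.0)
    return table.mean(axis=1)


def mask_structural_rna(
    assignments: Iterable[TaxonAssignment],
) -> list[TaxonAssignment]:
    """Drop assignments whose reads hit annotated rRNA/tRNA intervals."""
    return [a for a in assignments if not a.structural_rna]
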