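"""Taxon assignment (best-hit-then-LCA), rank rollups and the rRNA/tRNA
structural mask, checked against brute-force tree oracles."""
from __future__ import annotations

import numpy as np
import pytest

from exorna.errors import ConfigError, DataError
from exorna.matcher import MatchHit, build_index, find_matches
from exorna.reads import Read
from exorna.refdb import FeatureInterval, ReferenceDB
from exorna.synthetic import ErrorProfile, MixtureComponent, MixtureSpec, simulate_reads
from exorna.taxonomy import (
    TaxNode,
    TaxonAssignment,
    TaxonomyTree,
    assign_taxon,
    mask_structural_rna,
    rollup,
    rollup_mean,
)


@pytest.fixture(scope="module")
def tree():
    return TaxonomyTree(
        [
            TaxNode(1, 1, "root", "root"),
            TaxNode(2, 1, "kingdom", "Bacteria"),
            TaxNode(3, 2, "phylum", "Proteobacteria"),
            TaxNode(4, 2, "phylum", "Firmicutes"),
            TaxNode(5, 3, "genus", "Pseudomonas"),
            TaxNode(6, 5, "species", "P. fluorescens"),
            TaxNode(7, 5, "species", "P. putida"),
            TaxNode(8, 4, "genus", "Bacillus"),
            TaxNode(9, 8, "species", "B. subtilis"),
        ]
    )


def hit(seq_id, mismatches=0, start=0, read_id="r"):
    return MatchHit(read_id, "db", seq_id, start, "+", mismatches)


@pytest.fixture(scope="module")
def db():
    return ReferenceDB(
        "db",
        "microbiome",
        {"sA": "A" * 100, "sB": "C" * 100, "sC": "G" * 100},
        {"sA": 6, "sB": 7, "sC": 9},
        {"sA": [FeatureInterval("rRNA", 10, 40)]},
    )


class TestTree:
    def test_lineage_and_ranks(self, tree):
        assert tree.lineage(6) == [1, 2, 3, 5, 6]
        assert tree.ancestor_at_rank(6, "phylum") == 3
        assert tree.ancestor_at_rank(2, "phylum") is None

    def test_lca(self, tree):
        assert tree.lca([6, 7]) == 5
        assert tree.lca([6, 9]) == 2
        assert tree.lca([6]) == 6

    def test_round_trip_tsv(self, tree, tmp_path):
        path = tmp_path / "tax.tsv"
        tree.to_tsv(path)
        again = TaxonomyTree.from_tsv(path)
        assert again.nodes == tree.nodes

    def test_rejects_orphan_parent(self):
        with pytest.raises(ConfigError):
            TaxonomyTree([TaxNode(1, 1, "root", "root"), TaxNode(2, 99, "species", "x")])


class TestAssignTaxon:
    def test_single_species_hit(self, tree, db):
        a = assign_taxon([hit("sA")], db, tree, 23)
        assert (a.taxid, a.level) == (6, "species")

    def test_multiplicity_does_not_change_single_species_assignment(self, tree, db):
        a = assign_taxon([hit("sA", start=s) for s in (0, 5, 50)], db, tree, 23)
        assert (a.taxid, a.level) == (6, "species")

    def test_two_species_same_genus_equal_mismatch_gives_genus_lca(self, tree, db):
        a = assign_taxon([hit("sA"), hit("sB")], db, tree, 23)
        assert (a.taxid, a.level) == (5, "genus")

    def test_minimal_mismatch_filter_precedes_lca(self, tree, db):
        a = assign_taxon([hit("sA", mismatches=0), hit("sB", mismatches=2)], db, tree, 23)
        assert a.taxid == 6

    def test_cross_phylum_lca_is_kingdom(self, tree, db):
        a = assign_taxon([hit("sA"), hit("sC")], db, tree, 23)
        assert (a.taxid, a.level) == (2, "kingdom")

    def test_structural_flag_needs_one_base_overlap(self, tree, db):
        # feature is [10, 40): a 23-mer starting at 39 overlaps by one base
        assert assign_taxon([hit("sA", start=39)], db, tree, 23).structural_rna
        assert not assign_taxon([hit("sA", start=40)], db, tree, 23).structural_rna
        # overlap by a non-minimal hit does not flag the read
        a = assign_taxon([hit("sB", 0), hit("sA", 1, start=20)], db, tree, 23)
        assert not a.structural_rna

    def test_unknown_taxid_is_data_error(self, tree):
        bad = ReferenceDB("db", "microbiome", {"s": "A" * 50}, {"s": 777})
        with pytest.raises(DataError):
            assign_taxon([hit("s")], bad, tree, 23)

    def test_empty_hits_rejected(self, tree, db):
        with pytest.raises(DataError):
            assign_taxon([], db, tree, 23)

    def test_conserved_gene_reads_match_bruteforce_lca_oracle(self, community, taxid_of):
        """Reads simulated from a conserved rRNA gene shared by several taxa
        resolve exactly as a brute-force LCA over all minimal-distance hits."""
        dbs, tree = community
        db = dbs["microbiome"]
        mixture = MixtureSpec(
            [MixtureComponent("microbiome", taxid_of("Pseudomonas_f"), 1.0)],
            n_reads=500,
            seed=31,
        )
        reads, _ = simulate_reads(dbs, mixture, ErrorProfile.error_free(23))
        index = build_index(db, 23, 0)
        checked = 0
        for read in reads:
            hits = find_matches(index, read, 0)
            if not hits:
                continue
            a = assign_taxon(hits, db, tree, 23)
            # oracle: intersect full lineages of all minimal-mismatch taxa
            best = min(h.mismatches for h in hits)
            lineages = [
                tree.lineage(db.taxa[h.seq_id]) for h in hits if h.mismatches == best
            ]
            common = set(lineages[0]).intersection(*map(set, lineages[1:]))
            expected = max(common, key=lambda t: len(tree.lineage(t)))
            assert a.taxid == expected
            checked += 1
        assert checked == 500
        multi = [
            r for r in reads
            if len({db.taxa[h.seq_id] for h in find_matches(index, r, 0)}) > 1
        ]
        assert multi, "conserved gene should produce cross-taxon multi-mappers"


class TestRollup:
    def test_additivity(self, tree):
        assignments = (
            [TaxonAssignment(f"a{i}", 6, "species", False) for i in range(2)]
            + [TaxonAssignment(f"b{i}", 7, "species", False) for i in range(3)]
            + [TaxonAssignment(f"c{i}", 5, "genus", False) for i in range(5)]
        )
        counts = rollup(assignments, tree, "phylum")
        assert counts == {"Proteobacteria": 10}

    def test_unranked_bucket_and_conservation(self, tree):
        assignments = [
            TaxonAssignment("a", 6, "species", False),
            TaxonAssignment("b", 2, "kingdom", False),  # lineage lacks a phylum
        ]
        counts = rollup(assignments, tree, "phylum")
        assert counts == {"Proteobacteria": 1, "unranked": 1}
        assert sum(counts.values()) == len(assignments)

    def test_mean_across_samples_is_arithmetic_mean(self, tree):
        per_sample = {
            "s1": [TaxonAssignment("a", 6, "species", False)] * 2,
            "s2": [TaxonAssignment("b", 6, "species", False)] * 4
            + [TaxonAssignment("c", 9, "species", False)],
        }
        mean = rollup_mean(per_sample, tree, "phylum")
        assert mean["Proteobacteria"] == pytest.approx(3.0)
        assert mean["Firmicutes"] == pytest.approx(0.5)


class TestStructuralMask:
    def test_all_flagged_gives_empty_rollup(self, tree):
        assignments = [TaxonAssignment("a", 6, "species", True)] * 3
        assert rollup(mask_structural_rna(assignments), tree, "phylum") == {}

    def test_none_flagged_is_identity(self, tree):
        assignments = [TaxonAssignment(f"r{i}", 6, "species", False) for i in range(3)]
        assert mask_structural_rna(assignments) == assignments

    def test_masked_counts_pointwise_below_unmasked(self, tree):
        assignments = [
            TaxonAssignment(f"r{i}", t, "species", flag)
            for i, (t, flag) in enumerate(
                [(6, True), (6, False), (7, False), (9, True), (9, False)]
            )
        ]
        raw = rollup(assignments, tree, "phylum")
        masked = rollup(mask_structural_rna(assignments), tree, "phylum")
        for taxon, count in masked.items():
            assert count <= raw[taxon]

    def test_phylum_detected_only_through_conserved_gene_disappears(
        self, community, taxid_of
    ):
        """A phylum whose reads all come from its conserved rRNA gene is
        present in the raw rollup and absent after masking."""
        dbs, tree = community
        db = dbs["microbiome"]
        # reads exclusively from the Chloroflexus conserved 16S interval
        sid = next(s for s in db.features if s.startswith("Chloroflexus"))
        iv = db.features[sid][0]
        gene = db.sequences[sid][iv.start : iv.end]
        reads = [Read(f"g{i}", gene[i : i + 23]) for i in range(0, len(gene) - 23, 3)]
        index = build_index(db, 23, 0)
        assignments = []
        for read in reads:
            hits = find_matches(index, read, 0)
            assert hits, "conserved-gene reads must map to their own copy"
            assignments.append(assign_taxon(hits, db, tree, 23))
        raw = rollup(assignments, tree, "phylum")
        masked = rollup(mask_structural_rna(assignments), tree, "phylum")
        assert raw.get("Chloroflexi", 0) > 0
        assert "Chloroflexi" not in masked
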