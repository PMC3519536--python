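"""Generator and simulator: determinism, conserved-gene structure, truth
fidelity, and the statistical contracts of the error model."""
from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from exorna.errors import ConfigError, DataError
from exorna.reads import write_fastq
from exorna.refdb import ReferenceDB
from exorna.synthetic import (
    CommunityConfig,
    ConservedGeneConfig,
    DatabaseConfig,
    ErrorProfile,
    MixtureComponent,
    MixtureSpec,
    TaxonConfig,
    generate_reference_set,
    simulate_reads,
)


def two_taxon_config(divergence=0.02, seed=5):
    return CommunityConfig(
        seed=seed,
        databases=[
            DatabaseConfig(
                "bact",
                "microbiome",
                [
                    TaxonConfig("A_sp", 1, (1000, 1000), kingdom="Bacteria", phylum="P1"),
                    TaxonConfig("B_sp", 1, (1000, 1000), kingdom="Bacteria", phylum="P1"),
                ],
                conserved_genes=[
                    ConservedGeneConfig("16S", "rRNA", 200, divergence, ["A_sp", "B_sp"])
                ],
            )
        ],
    )


class TestGenerateReferenceSet:
    def test_deterministic_under_fixed_seed(self):
        cfg = CommunityConfig(
            [DatabaseConfig("t", "transcripts", [TaxonConfig("X", 1, (1000, 1000), gc=0.5)])],
            seed=3,
        )
        dbs1, _ = generate_reference_set(cfg)
        dbs2, _ = generate_reference_set(cfg)
        assert dbs1["t"].sequences == dbs2["t"].sequences

    def test_conserved_gene_copies_annotated_and_similar(self):
        dbs, _ = generate_reference_set(two_taxon_config())
        db = dbs["bact"]
        copies = []
        for sid, ivals in db.features.items():
            assert len(ivals) == 1 and ivals[0].kind == "rRNA"
            iv = ivals[0]
            copies.append(db.sequences[sid][iv.start : iv.end])
        assert len(copies) == 2 and len(copies[0]) == 200
        identity = sum(a == b for a, b in zip(*copies)) / 200
        assert identity >= 0.95

    def test_every_sequence_taxon_resolvable_and_rollup_to_one_phylum(self):
        dbs, tree = generate_reference_set(two_taxon_config())
        db = dbs["bact"]
        phyla = set()
        for sid in db.sequences:
            tid = db.taxid_of(sid)
            assert tid in tree
            phyla.add(tree.ancestor_at_rank(tid, "phylum"))
        assert len(phyla) == 1
        assert tree.name(phyla.pop()) == "P1"

    def test_gc_content_respected(self):
        cfg = CommunityConfig(
            [DatabaseConfig("t", "transcripts", [TaxonConfig("X", 1, (50000, 50000), gc=0.7)])],
            seed=1,
        )
        dbs, _ = generate_reference_set(cfg)
        seq = next(iter(dbs["t"].sequences.values()))
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.7) < 0.01

    @pytest.mark.parametrize(
        "bad_taxon",
        [
            dict(name="X", n_sequences=1, length_range=(0, 10)),
            dict(name="X", n_sequences=1, length_range=(10, 5)),
            dict(name="X", n_sequences=1, length_range=(10, 20), gc=1.5),
            dict(name="X", n_sequences=0, length_range=(10, 20)),
        ],
    )
    def test_invalid_config_rejected(self, bad_taxon):
        with pytest.raises(ConfigError):
            TaxonConfig(**bad_taxon)


class TestErrorProfile:
    def test_rate_vector_must_cover_every_cycle(self):
        with pytest.raises(ConfigError):
            ErrorProfile(23, np.zeros(22), np.full(23, 30.0))

    def test_rates_must_be_probabilities(self):
        with pytest.raises(ConfigError):
            ErrorProfile(5, np.array([0, 0, 1.5, 0, 0]), np.full(5, 30.0))

    def test_illumina_like_mean_rate(self):
        prof = ErrorProfile.illumina_like(23, 0.01)
        assert prof.per_cycle_sub_rate.mean() == pytest.approx(0.01, rel=1e-9)
        # 3' end worse than 5' end, Illumina-style
        assert prof.per_cycle_sub_rate[-1] > prof.per_cycle_sub_rate[0]


class TestSimulateReads:
    def test_zero_error_reads_are_exact_source_substrings(self, community, taxid_of):
        dbs, _ = community
        mixture = MixtureSpec(
            [MixtureComponent("host_genome", taxid_of("Homo"), 1.0)], 300, seed=2
        )
        reads, truths = simulate_reads(dbs, mixture, ErrorProfile.error_free(23))
        from exorna._seq import revcomp

        seen_minus = False
        for read, truth in zip(reads, truths):
            assert truth.error_positions == ()
            window = dbs["host_genome"].sequences[truth.seq_id][truth.start : truth.end]
            if truth.strand == "-":
                window = revcomp(window)
                seen_minus = True
            assert read.seq == window
        assert seen_minus, "genome-type reads should come from both strands"

    def test_transcript_reads_are_sense_strand_only(self, plasma_reads):
        _reads, truths, _ = plasma_reads
        transcript_truths = [t for t in truths if t.db_id in ("host_transcripts", "food")]
        assert transcript_truths
        assert all(t.strand == "+" for t in transcript_truths)

    def test_truth_counts_conserve_n_reads(self, plasma_reads):
        reads, truths, mixture = plasma_reads
        assert len(reads) == len(truths) == mixture.n_reads
        assert len({r.read_id for r in reads}) == mixture.n_reads

    def test_component_counts_within_multinomial_bounds(self, community, taxid_of):
        dbs, _ = community
        mixture = MixtureSpec(
            [
                MixtureComponent("host_transcripts", taxid_of("Homo"), 0.9),
                MixtureComponent("microbiome", taxid_of("Pseudomonas_f"), 0.1),
            ],
            n_reads=10_000,
            seed=4,
        )
        _reads, truths = simulate_reads(dbs, mixture, ErrorProfile.error_free(23))
        host_taxid = taxid_of("Homo")
        n_host = sum(t.taxid == host_taxid for t in truths)
        sd = np.sqrt(10_000 * 0.9 * 0.1)
        assert abs(n_host - 9000) <= 3 * sd

    def test_error_statistics_match_profile(self, community, taxid_of):
        """Mean errors/read, >=3-error tail and per-cycle chi-square GOF."""
        dbs, _ = community
        L, rate, n = 23, 0.01, 100_000
        profile = ErrorProfile(L, np.full(L, rate), np.full(L, 30.0))
        mixture = MixtureSpec(
            [MixtureComponent("host_genome", taxid_of("Homo"), 1.0)], n, seed=6
        )
        _reads, truths = simulate_reads(dbs, mixture, profile)
        errs_per_read = np.array([len(t.error_positions) for t in truths])
        mean_expected = L * rate
        assert abs(errs_per_read.mean() - mean_expected) <= 3 * np.sqrt(mean_expected / n)
        # >=3-error tail follows the closed-form Binomial(L, rate) tail
        tail = float(stats.binom.sf(2, L, rate))
        n_tail = int((errs_per_read >= 3).sum())
        assert abs(n_tail - n * tail) <= 3 * np.sqrt(n * tail * (1 - tail)) + 1
        # chi-square goodness of fit: per-cycle error counts are uniform
        # across cycles (conditioning on the observed total)
        per_cycle = np.zeros(L)
        for t in truths:
            for pos in t.error_positions:
                per_cycle[pos] += 1
        chi2, p = stats.chisquare(per_cycle, f_exp=np.full(L, per_cycle.sum() / L))
        assert p > 0.01

    def test_byte_identical_fastq_for_fixed_seed(self, community, taxid_of, tmp_path):
        dbs, _ = community
        mixture = MixtureSpec(
            [MixtureComponent("fungi", taxid_of("Metarhizium_a"), 1.0)], 200, seed=9
        )
        profile = ErrorProfile.illumina_like(23, 0.01)
        for name in ("a.fastq", "b.fastq"):
            reads, _ = simulate_reads(dbs, mixture, profile)
            write_fastq(reads, tmp_path / name)
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()

    def test_empty_source_pool_is_a_data_error(self, community):
        dbs, _ = community
        mixture = MixtureSpec([MixtureComponent("fungi", 999_999, 1.0)], 10, seed=0)
        with pytest.raises(DataError, match="empty source pool"):
            simulate_reads(dbs, mixture, ErrorProfile.error_free(23))

    def test_weights_must_be_positive(self):
        with pytest.raises(ConfigError):
            MixtureSpec([MixtureComponent("x", 1, 0.0)], 10)
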