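"""End-to-end experiment drivers shared by the analysis scripts, the test
suite and the acceptance script.

Two validation experiments defend the pipeline the same way the original
study design does:

* ``simulated_transcriptome_recovery`` — reads simulated from a transcriptome
  with an Illumina-like error profile must map back to it almost completely
  (>= 98%) under a 2-mismatch tolerance, showing the cascade does not lose
  genuine endogenous reads.
* ``negative_control_coincidence`` — reads simulated from a single source
  genome, run through the full cascade against unrelated exogenous
  databases, must essentially never be called exogenous: chance 0-mismatch
  matches of 23-nt reads in ~50 Mb of foreign sequence are vanishingly rare,
  so any real exogenous signal well above that floor cannot be a sequencing
  -error artifact.

Problem sizes (2,000 transcripts; 12 Mb host + ~50 Mb foreign genomes;
1-2x10^5 reads) are the package's desk-scale study conditions: large enough
for stable fractions, small enough to regenerate from scratch on a laptop.
"""
from __future__ import annotations

import numpy as np

from .classify import (
    POLICY_FIXED0,
    POLICY_STRATEGY,
    Tier,
    TierSpec,
    category_fractions,
    run_map_and_remove,
)
from .synthetic import (
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


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive independent 31-bit sub-seeds from one master seed."""
    return [int(s) for s in np.random.default_rng(seed).integers(0, 2**31, size=n)]


def simulated_transcriptome_recovery(
    seed: int,
    n_transcripts: int = 2000,
    length_range: tuple[int, int] = (500, 2000),
    n_reads: int = 100_000,
    read_length: int = 23,
    mean_error_rate: float = 0.01,
) -> dict:
    """Simulate reads from a synthetic transcriptome and map them back at
    2-mismatch tolerance; returns the mapped percentage and run metadata."""
    community_seed, mixture_seed = _spawn_seeds(seed, 2)
    config = CommunityConfig(
        databases=[
            DatabaseConfig(
                "transcriptome",
                "transcripts",
                [TaxonConfig("SimHost", n_transcripts, length_range, kingdom="Animalia")],
            )
        ],
        seed=community_seed,
    )
    dbs, _tree = generate_reference_set(config)
    taxid = next(iter(dbs["transcriptome"].taxa.values()))
    profile = ErrorProfile.illumina_like(read_length, mean_error_rate)
    mixture = MixtureSpec(
        [MixtureComponent("transcriptome", taxid, 1.0)], n_reads, seed=mixture_seed
    )
    reads, truths = simulate_reads(dbs, mixture, profile)
    tiers = TierSpec([Tier("transcriptome", "Endogenous", POLICY_STRATEGY)])
    table = run_map_and_remove(reads, dbs, tiers, strategy=2)
    frac = category_fractions(table)
    return {
        "mapped_percent": frac["Endogenous"],
        "unmapped_percent": frac["unmapped"],
        "n_reads": n_reads,
        "n_transcripts": n_transcripts,
        "read_length": read_length,
        "mean_error_rate": mean_error_rate,
        "mean_errors_per_read": float(np.mean([len(t.error_positions) for t in truths])),
    }


def negative_control_coincidence(
    seed: int,
    n_reads: int = 200_000,
    read_length: int = 23,
    error_rate: float = 0.005,
    host_chunks: int = 4,
    host_chunk_len: int = 3_000_000,
    exo_sizes: dict[str, tuple[int, int]] | None = None,
) -> dict:
    """Full cascade on reads from a lone host genome vs unrelated exogenous
    databases; returns the percentage called exogenous (the coincidence
    floor) plus per-category fractions.

    Defaults: 12 Mb host genome; exogenous tiers are independent random
    genomes totalling ~50 Mb (20 Mb "bacteria", 18 Mb "fungi", 12 Mb
    "other"); host tier searched at Strategy 2, exogenous tiers exact-only.
    """
    if exo_sizes is None:
        exo_sizes = {"bacteria": (2, 10_000_000), "fungi": (2, 9_000_000), "other": (2, 6_000_000)}
    community_seed, mixture_seed = _spawn_seeds(seed, 2)
    databases = [
        DatabaseConfig(
            "host_genome",
            "genome",
            [TaxonConfig("SimHost", host_chunks, (host_chunk_len, host_chunk_len), kingdom="Animalia")],
        )
    ]
    for name, (n_seqs, size) in exo_sizes.items():
        databases.append(
            DatabaseConfig(
                name,
                "microbiome" if name == "bacteria" else "nt",
                [TaxonConfig(f"Sim{name.capitalize()}", n_seqs, (size, size), kingdom=name)],
            )
        )
    config = CommunityConfig(databases=databases, seed=community_seed)
    dbs, _tree = generate_reference_set(config)
    host_taxid = next(iter(dbs["host_genome"].taxa.values()))
    profile = ErrorProfile.illumina_like(read_length, error_rate)
    mixture = MixtureSpec(
        [MixtureComponent("host_genome", host_taxid, 1.0)], n_reads, seed=mixture_seed
    )
    reads, _truths = simulate_reads(dbs, mixture, profile)
    tiers = TierSpec(
        [Tier("host_genome", "Endogenous", POLICY_STRATEGY)]
        + [Tier(name, name.capitalize(), POLICY_FIXED0) for name in exo_sizes]
    )
    table = run_map_and_remove(reads, dbs, tiers, strategy=2)
    frac = category_fractions(table)
    exo_percent = sum(frac[name.capitalize()] for name in exo_sizes)
    exo_total = sum(n * size for n, size in exo_sizes.values())
    return {
        "exogenous_percent": exo_percent,
        "fractions": frac,
        "n_reads": n_reads,
        "host_bp": host_chunks * host_chunk_len,
        "exogenous_bp": exo_total,
        "read_length": read_length,
        "error_rate": error_rate,
    }


def demo_plasma_community(seed: int = 0, scale: float = 1.0) -> CommunityConfig:
    """A small plasma-like community for the worked analyses: host tiers, a
    bacterial tier whose taxa share conserved rRNA/tRNA genes, a fungal
    tier, food-plant transcript pools and an exogenous miRNA set.

    ``scale`` multiplies sequence lengths (not counts), letting tests shrink
    the community without changing its structure.
    """

    def rng_len(lo: int, hi: int) -> tuple[int, int]:
        return (max(int(lo * scale), 60), max(int(hi * scale), 80))

    return CommunityConfig(
        seed=seed,
        databases=[
            DatabaseConfig(
                "host_mirna",
                "miRNA",
                [TaxonConfig("Homo", 50, (21, 23), kingdom="Animalia", phylum="Chordata")],
            ),
            DatabaseConfig(
                "host_transcripts",
                "transcripts",
                [TaxonConfig("Homo", 80, rng_len(500, 2000), kingdom="Animalia", phylum="Chordata")],
            ),
            DatabaseConfig(
                "host_genome",
                "genome",
                [TaxonConfig("Homo", 4, rng_len(20_000, 30_000), kingdom="Animalia", phylum="Chordata")],
            ),
            DatabaseConfig(
                "microbiome",
                "microbiome",
                [
                    TaxonConfig("Pseudomonas_f", 3, rng_len(4000, 8000), kingdom="Bacteria", phylum="Proteobacteria"),
                    TaxonConfig("Ralstonia_x", 3, rng_len(4000, 8000), kingdom="Bacteria", phylum="Proteobacteria"),
                    TaxonConfig("Bacteroides_y", 3, rng_len(4000, 8000), kingdom="Bacteria", phylum="Bacteroidetes"),
                    TaxonConfig("Chloroflexus_z", 2, rng_len(3000, 6000), kingdom="Bacteria", phylum="Chloroflexi"),
                ],
                conserved_genes=[
                    ConservedGeneConfig(
                        "16S", "rRNA", 150, 0.02,
                        ["Pseudomonas_f", "Ralstonia_x", "Bacteroides_y", "Chloroflexus_z"],
                    ),
                    ConservedGeneConfig(
                        "tRNA-Ala", "tRNA", 75, 0.05,
                        ["Pseudomonas_f", "Ralstonia_x", "Bacteroides_y"],
                    ),
                ],
            ),
            DatabaseConfig(
                "fungi",
                "nt",
                [
                    TaxonConfig("Metarhizium_a", 3, rng_len(4000, 8000), kingdom="Fungi", phylum="Ascomycota"),
                    TaxonConfig("Thielavia_t", 3, rng_len(4000, 8000), kingdom="Fungi", phylum="Ascomycota"),
                    TaxonConfig("Rhizopus_b", 2, rng_len(3000, 6000), kingdom="Fungi", phylum="Zygomycota"),
                ],
                conserved_genes=[
                    ConservedGeneConfig(
                        "18S", "rRNA", 150, 0.02,
                        ["Metarhizium_a", "Thielavia_t", "Rhizopus_b"],
                    )
                ],
            ),
            DatabaseConfig(
                "food",
                "transcripts",
                [
                    TaxonConfig("Zea_mays", 10, rng_len(500, 1500), kingdom="Plantae", phylum="Streptophyta"),
                    TaxonConfig("Oryza_sativa", 10, rng_len(500, 1500), kingdom="Plantae", phylum="Streptophyta"),
                    TaxonConfig("Glycine_max", 6, rng_len(500, 1500), kingdom="Plantae", phylum="Streptophyta"),
                ],
            ),
            DatabaseConfig(
                "exo_mirna",
                "exo_miRNA",
                [
                    TaxonConfig("Aedes_m", 20, (21, 23), kingdom="Animalia", phylum="Arthropoda"),
                    TaxonConfig("Bombyx_m", 20, (21, 23), kingdom="Animalia", phylum="Arthropoda"),
                ],
            ),
        ],
    )
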