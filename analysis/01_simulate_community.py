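#!/usr/bin/env python
"""Build the synthetic plasma-like community and simulate 9 plasma samples.

Writes the reference tiers (FASTA + taxon TSV + rRNA/tRNA BED), the taxonomy
table, and per-sample FASTQ + ground-truth tables under results/community/.
The community deliberately contains the structures the classification has to
cope with: a dominant host, bacterial taxa sharing conserved 16S/tRNA genes,
fungi, food plants at unequal abundance, and foreign miRNAs.
"""
from pathlib import Path

from exorna.experiments import demo_plasma_community
from exorna.reads import write_fastq
from exorna.refdb import write_db
from exorna.synthetic import (
    ErrorProfile,
    MixtureComponent,
    MixtureSpec,
    generate_reference_set,
    simulate_reads,
    truth_to_tsv,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "community"
N_SAMPLES = 9
READS_PER_SAMPLE = 5000


def plasma_mixture(tree, n_reads: int, seed: int) -> MixtureSpec:
    taxid = {tree.name(t): t for t in tree.nodes}
    return MixtureSpec(
        [
            MixtureComponent("host_mirna", taxid["Homo"], 0.013),
            MixtureComponent("host_transcripts", taxid["Homo"], 0.535),
            MixtureComponent("host_genome", taxid["Homo"], 0.15),
            MixtureComponent("exo_mirna", taxid["Aedes_m"], 0.002),
            MixtureComponent("microbiome", taxid["Pseudomonas_f"], 0.08),
            MixtureComponent("microbiome", taxid["Ralstonia_x"], 0.04),
            MixtureComponent("microbiome", taxid["Bacteroides_y"], 0.03),
            MixtureComponent("microbiome", taxid["Chloroflexus_z"], 0.01),
            MixtureComponent("fungi", taxid["Metarhizium_a"], 0.05),
            MixtureComponent("fungi", taxid["Thielavia_t"], 0.04),
            MixtureComponent("food", taxid["Zea_mays"], 0.033),
            MixtureComponent("food", taxid["Oryza_sativa"], 0.0005),
            MixtureComponent("food", taxid["Glycine_max"], 0.0165),
        ],
        n_reads=n_reads,
        seed=seed,
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = demo_plasma_community(seed=2024)
    dbs, tree = generate_reference_set(config)
    for db_id, db in dbs.items():
        write_db(db, OUT / db_id)
    tree.to_tsv(OUT / "taxonomy.tsv")
    print(f"reference tiers: {', '.join(f'{k} ({v.total_length:,} bp)' for k, v in dbs.items())}")

    profile = ErrorProfile.illumina_like(23, 0.01)
    for s in range(N_SAMPLES):
        mixture = plasma_mixture(tree, READS_PER_SAMPLE, seed=3000 + s)
        reads, truths = simulate_reads(dbs, mixture, profile)
        write_fastq(reads, OUT / f"sample{s + 1}.fastq")
        truth_to_tsv(truths, OUT / f"sample{s + 1}.truth.tsv")
    print(f"simulated {N_SAMPLES} samples x {READS_PER_SAMPLE} reads (23 nt, 1% mean "
          f"substitution) -> {OUT}")


if __name__ == "__main__":
    main()
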