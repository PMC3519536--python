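"""Shared fixtures: a small plasma-like synthetic community and simulated
read sets with ground truth, regenerated deterministically at test time."""
from __future__ import annotations

import numpy as np
import pytest

from exorna.experiments import demo_plasma_community
from exorna.synthetic import (
    ErrorProfile,
    MixtureComponent,
    MixtureSpec,
    generate_reference_set,
    simulate_reads,
)


@pytest.fixture(scope="session")
def community():
    """(dbs, tree) for a down-scaled plasma-like community: host tiers,
    bacteria with shared rRNA/tRNA genes, fungi, food plants, foreign miRNA."""
    return generate_reference_set(demo_plasma_community(seed=11, scale=0.25))


@pytest.fixture(scope="session")
def taxid_of(community):
    _dbs, tree = community

    def lookup(name: str) -> int:
        for tid, node in tree.nodes.items():
            if node.name == name:
                return tid
        raise KeyError(name)

    return lookup


@pytest.fixture(scope="session")
def plasma_reads(community, taxid_of):
    """Error-free 23-nt reads from host transcripts, bacteria, fungi and food,
    with truth records; host-dominant proportions."""
    dbs, _tree = community
    mixture = MixtureSpec(
        [
            MixtureComponent("host_transcripts", taxid_of("Homo"), 0.70),
            MixtureComponent("microbiome", taxid_of("Pseudomonas_f"), 0.10),
            MixtureComponent("microbiome", taxid_of("Bacteroides_y"), 0.05),
            MixtureComponent("fungi", taxid_of("Metarhizium_a"), 0.08),
            MixtureComponent("food", taxid_of("Zea_mays"), 0.05),
            MixtureComponent("food", taxid_of("Oryza_sativa"), 0.02),
        ],
        n_reads=2000,
        seed=17,
    )
    reads, truths = simulate_reads(dbs, mixture, ErrorProfile.error_free(23))
    return reads, truths, mixture


@pytest.fixture()
def rng():
    return np.random.default_rng(20250925)
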