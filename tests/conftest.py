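import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")

from phyloindel import (
    GappedAlignment,
    Phylogeny,
    SequenceRecord,
    SimulationConfig,
    simulate_study,
    species_consensus_alignment,
)


@pytest.fixture(scope="session")
def five_taxon_tree():
    """Four ingroup taxa plus outgroup O, ultrametric."""
    return Phylogeny.from_newick(
        "(((A:1,B:1):1,(C:1,D:1):1):1,O:3);", outgroup="O"
    )


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study reused across read-only tests."""
    return simulate_study(seed=1)


@pytest.fixture(scope="session")
def default_species_alignment(default_study):
    aln, reports = species_consensus_alignment(default_study["alignment"])
    return aln, reports


@pytest.fixture(scope="session")
def small_selection_study():
    """Scaled-down study with a positively selected site class."""
    cfg = SimulationConfig(
        n_species=8,
        n_codons=150,
        indel_rate=0.3,
        site_classes=[(0.45, 0.1), (0.4, 1.0), (0.15, 4.0)],
    )
    return simulate_study(cfg, seed=11)


def make_alignment(seqs: dict[str, str], outgroup: str | None = None):
    records = [
        SequenceRecord(name, seq, is_outgroup=(name == outgroup))
        for name, seq in seqs.items()
    ]
    return GappedAlignment(records)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
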