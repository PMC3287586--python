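import pytest

from litpath.orthology import ProteinDatabase, calibrate_min_score
from litpath.resources import default_lexicon
from litpath.synth import (ProteomeConfig, default_gene_dictionary,
                           make_proteome, make_taxonomy)

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def mini_tax():
    return make_taxonomy()


@pytest.fixture(scope="session")
def gene_dictionary():
    return default_gene_dictionary()


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


SIX_TAXA = [9606, 10090, 7955, 7227, 8364, 9031]


@pytest.fixture(scope="session")
def proteome_fixture():
    """5 families x 6 taxa at substitution rate 0.05 with 10% decoys."""
    config = ProteomeConfig(taxa=SIX_TAXA, families=5, family_size_range=(6, 6),
                            mutation_rate=0.05, decoy_rate=0.1,
                            complete_genome_taxa=frozenset({9606, 10090}),
                            rng_seed=42)
    records, partition = make_proteome(config)
    return config, records, partition


@pytest.fixture(scope="session")
def protein_db(proteome_fixture):
    _, records, _ = proteome_fixture
    return ProteinDatabase(records)


@pytest.fixture(scope="session")
def calibrated_floor(protein_db, proteome_fixture):
    _, _, partition = proteome_fixture
    return calibrate_min_score(protein_db, partition)
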