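import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from stabilimeta import synthio


@pytest.fixture(scope="session")
def small_config():
    """A small but fully-featured community: 3 taxa x 4 species."""
    return synthio.SimConfig(
        species_per_taxon=4,
        reads_per_sample=1000,
        n_samples_per_method=(3, 3),
        n_genes_per_taxon=60,
        n_mrna_samples_per_method=2,
        mrna_depth=2.0e5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return synthio.build_ground_truth(small_config)


@pytest.fixture(scope="session")
def small_rrna(small_config, small_truth):
    return synthio.simulate_rrna_samples(small_config, small_truth)


@pytest.fixture(scope="session")
def small_mrna(small_config, small_truth):
    return synthio.simulate_mrna_samples(small_config, small_truth)
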