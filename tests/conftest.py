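import pytest

from bescan.synthetic_data import (
    SyntheticGenomeSpec,
    alba_fixture,
    simulate_genome,
)

STRATEGY_NAME = {
    "stop": "premature_stop",
    "start": "start_loss",
    "splice": "splice_disruption",
}


@pytest.fixture(scope="session")
def alba():
    """(sequences, [gene]) for the albA-like 5-exon fixture gene."""
    return alba_fixture()


@pytest.fixture(scope="session")
def sim100():
    """Seeded 100-gene synthetic genome with its planted-truth manifest."""
    spec = SyntheticGenomeSpec(n_genes=100, seed=11)
    return simulate_genome(spec)


@pytest.fixture(scope="session")
def sim_small():
    """Smaller genome for the more expensive whole-pipeline properties."""
    spec = SyntheticGenomeSpec(n_genes=25, seed=7)
    return simulate_genome(spec)
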