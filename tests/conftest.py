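import numpy as np
import pytest
from hypothesis import settings

from ppicontext.orthology import OrthologTable
from ppicontext.synthetic_data import SimulationConfig, simulate_corpus

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def strong_corpus():
    """Default 60-genome corpus with strongly coupled planted pairs."""
    return simulate_corpus(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_corpus():
    """A quick corpus for integration and I/O tests."""
    from ppicontext.synthetic_data import CoevolutionSpec, OperonSpec

    config = SimulationConfig(
        n_genomes=14,
        n_proteins=20,
        n_interacting_pairs=5,
        operon_spec=OperonSpec(n_operons=5),
        coevolution_spec=CoevolutionSpec(alignment_length=60),
        chromosome_length=200_000,
        seed=42,
    )
    return simulate_corpus(config)


@pytest.fixture
def toy_table():
    """Three proteins, four genomes, hand-written entries."""
    entries = {
        ("A", "g1"): ("a1", 100.0),
        ("A", "g2"): ("a2", 90.0),
        ("A", "g3"): ("a3", 80.0),
        ("B", "g1"): ("b1", 200.0),
        ("B", "g2"): ("b2", 150.0),
        ("C", "g4"): ("c4", 50.0),
    }
    return OrthologTable(entries, ["g1", "g2", "g3", "g4"], ["A", "B", "C"])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
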