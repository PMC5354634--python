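import numpy as np
import pytest

from tecpause.energy_model import build_energy_profile, build_energy_table
from tecpause.io_formats import GeneInterval, build_concatenated_transcriptome
from tecpause.synthetic_data import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def dna_table():
    return build_energy_table("DNA:DNA")


@pytest.fixture(scope="session")
def rna_table():
    return build_energy_table("RNA:DNA")


@pytest.fixture(scope="session")
def mismatch_table():
    return build_energy_table("RNA:DNA-mismatch")


def _random_genome(rng, n=4000, gc=0.4):
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])


@pytest.fixture(scope="session")
def small_transcriptome():
    """Two genes (one per strand) on one random chromosome."""
    rng = np.random.default_rng(7)
    genome = {"chrI": _random_genome(rng)}
    genes = [
        GeneInterval("chrI", 100, 1600, "+", "geneA"),
        GeneInterval("chrI", 2000, 3800, "-", "geneB"),
    ]
    return build_concatenated_transcriptome(genome, genes), genome, genes


@pytest.fixture(scope="session")
def small_profile(small_transcriptome):
    tx, _, _ = small_transcriptome
    return build_energy_profile(tx)


@pytest.fixture(scope="session")
def default_dataset():
    """The default-conditions synthetic dataset used by end-to-end checks."""
    return generate_dataset(SyntheticSpec(seed=1))
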