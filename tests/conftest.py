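import numpy as np
import pytest

from genustax import _sw
from genustax.synthetic_data import SimulationConfig, simulate_pangenome

AA = "ACDEFGHIKLMNPQRSTVWY"
NT = "ACGT"


@pytest.fixture(scope="session", autouse=True)
def _jit_warmup():
    _sw.warm_up()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_protein(rng, length):
    return "".join(rng.choice(list(AA), size=length))


def random_nucleotide(rng, length):
    return "".join(rng.choice(list(NT), size=length))


@pytest.fixture(scope="session")
def small_simulation():
    """3 genera x 2 genomes, 30 core genes — enough structure for most
    pipeline-level tests while staying fast."""
    config = SimulationConfig(
        seed=11, n_genera=3, genomes_per_genus=2, n_core=30,
        gene_len_range=(120, 200),
    )
    return simulate_pangenome(config)


@pytest.fixture(scope="session")
def null_simulation():
    """No gain/loss/duplication and tiny divergence: planted orthology is
    a clean 1:1 matching everywhere."""
    config = SimulationConfig(
        seed=5, n_genera=2, genomes_per_genus=2, n_core=25,
        intra_depth=0.1, inter_depth=0.2,
        gain_rate=0.0, loss_rate=0.0, dup_prob=0.0,
        gene_len_range=(120, 200),
    )
    return simulate_pangenome(config)
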