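import numpy as np
import pytest

from hybridload import AlleleRegistry, Population, SimulationParams
from hybridload.genome_model import OUTCROSSER, SELFER


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


@pytest.fixture
def registry():
    return AlleleRegistry(alpha=7.0)


@pytest.fixture
def small_params():
    return SimulationParams(
        n_pop=20,
        n_loc=10,
        r=0.1,
        mu=1e-3,
        t1=10,
        t_post=10,
        n_replicates=2,
        record_every=5,
        seed=7,
    )


def make_population(alleles, registry, sigma=0.0, label="outcrosser", ancestry=None):
    """Build a Population from an (N, 2, L) allele-id array."""
    alleles = np.asarray(alleles)
    if ancestry is None:
        tag = OUTCROSSER if label == "outcrosser" else SELFER
        ancestry = np.full(alleles.shape, tag, dtype=np.int8)
    return Population(alleles, ancestry, sigma, label, registry)
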