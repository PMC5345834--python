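import numpy as np
import pytest

from genospec.synthetic_data import SimulationConfig, simulate_species_complex


@pytest.fixture(scope="session")
def small_complex():
    """Three planted species (sizes 3/2/1), 60 kb genomes: fast enough for
    per-module tests while still straddling the species thresholds."""
    cfg = SimulationConfig(cluster_sizes=[3, 2, 1], genome_length=60_000,
                           seed=11)
    return simulate_species_complex(cfg)


@pytest.fixture(scope="session")
def subspecies_complex():
    """One 4-strain species with two planted subspecies plus two smaller
    species; used for subspecies-cut tests."""
    cfg = SimulationConfig(cluster_sizes=[4, 2, 1], genome_length=60_000,
                           seed=7)
    return simulate_species_complex(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
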