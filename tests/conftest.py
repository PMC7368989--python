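import numpy as np
import pytest

from sexchrom.simulate import (SimulationConfig, simulate_bacs,
                               simulate_genome, simulate_tracks_and_counts)


@pytest.fixture(scope="session")
def sim():
    """The standard desk-scale genome used by the truth-recovery tests."""
    genome, _ = simulate_genome(SimulationConfig(seed=7))
    return genome


@pytest.fixture(scope="session")
def bacs(sim):
    bac_seqs, _ = simulate_bacs(sim)
    return bac_seqs


@pytest.fixture(scope="session")
def tracks(sim):
    return simulate_tracks_and_counts(sim)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def small_config(**overrides):
    """A fast, reduced genome for unit tests that need their own run."""
    base = dict(seed=5, n_autosomes=2, autosome_len=60_000, x_len=60_000,
                par_len=10_000, genes_per_stratum=(8, 6, 7),
                genes_per_autosome=6, cds_codons=120, n_gaps=3,
                n_translocations=2, n_translocation_duplicated=1,
                n_duplications=2, n_unknown_genes=2, n_unknown_duplicated=1,
                n_monomers=12, n_bacs=8)
    base.update(overrides)
    return SimulationConfig(**base)
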