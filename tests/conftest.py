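import pytest

from longapa.simulate import SimConfig, simulate_genome, simulate_reads, reads_to_endsites


@pytest.fixture(scope="session")
def small_sim():
    """A small three-stage synthetic dataset shared across tests."""
    cfg = SimConfig(n_genes=40, seed=11)
    sim = simulate_genome(cfg)
    reads = simulate_reads(cfg, sim.truth)
    return cfg, sim, reads


@pytest.fixture(scope="session")
def small_sites(small_sim):
    _, _, reads = small_sim
    return reads_to_endsites(reads)
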