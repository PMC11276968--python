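import pytest

from ucekit.simulate import SimConfig, simulate_genomes


@pytest.fixture(scope="session")
def small_sim():
    """A small genome set without the high-copy repeat element."""
    cfg = SimConfig(
        seed=101, n_species=4, genome_length=30_000, n_elements=10,
        n_repeat_copies=1,
    )
    gs, truth = simulate_genomes(cfg)
    return gs, truth


@pytest.fixture(scope="session")
def repeat_sim():
    """Default study conditions including the 150-copy repeat element."""
    cfg = SimConfig(seed=202)
    gs, truth = simulate_genomes(cfg)
    return gs, truth
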