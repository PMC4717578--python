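import numpy as np
import pytest

from trimscape.synthetic_data import SimulationSpec, simulate_genome


@pytest.fixture(scope="session")
def small_sim():
    """100-kb genome, 10 identical-copy elements (divergence 0)."""
    spec = SimulationSpec(
        genome_length=100_000, n_trims=10, divergence=0.0, seed=1, n_subfamilies=2
    )
    return simulate_genome(spec)


@pytest.fixture(scope="session")
def diverged_sim():
    """150-kb genome, 12 elements at 2% divergence plus solos and genes."""
    spec = SimulationSpec(
        genome_length=150_000,
        n_trims=12,
        n_solo_ltrs=2,
        n_genes=5,
        divergence=0.02,
        seed=5,
        n_subfamilies=3,
    )
    return simulate_genome(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def embed(background: str, pos: int, element: str, tsd: str = "") -> str:
    """Insert element with a TSD duplication at *pos* (host-style)."""
    return background[:pos] + tsd + element + tsd + background[pos:]
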