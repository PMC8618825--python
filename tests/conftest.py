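import numpy as np
import pytest

from newgene.simulate import SimulationConfig, simulate_ladder


def small_config(seed: int = 1) -> SimulationConfig:
    """Desk-scale world: one 300 kb chromosome, 40 ancestral genes, 16
    planted events (one per mechanism-lean mix per young branch)."""
    return SimulationConfig(
        seed=seed,
        n_chromosomes=1,
        chromosome_length=300_000,
        n_ancestral_genes=40,
        events_per_branch={
            b: {"dna_duplication": 2, "retroposition": 1, "de_novo": 1}
            for b in (2, 3, 4, 5)
        },
    )


@pytest.fixture(scope="session")
def small_sim():
    return simulate_ladder(small_config(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
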