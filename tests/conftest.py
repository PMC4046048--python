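import numpy as np
import pytest

from concordqtl import simulate as sim


@pytest.fixture(scope="session")
def small_pop():
    """A small synthetic population shared by read-only tests."""
    cfg = sim.SimulationConfig(
        n_animals=120,
        n_sequenced=60,
        n_seq_variants=400,
        qtl_variant_index=195,
        seed=7,
    )
    return sim.simulate_population(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
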