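import numpy as np
import pytest

from coremod import metnet, synth


@pytest.fixture(scope="session")
def small_cfg() -> synth.SyntheticConfig:
    return synth.SyntheticConfig(
        n_genes=60,
        n_reactions=80,
        n_samples_per_state=20,
        planted_module_size=8,
        known_gene_count=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_cfg) -> synth.SyntheticBundle:
    return synth.generate(small_cfg)


@pytest.fixture(scope="session")
def small_net(small_bundle):
    return metnet.build_network(small_bundle.reaction_table)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
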