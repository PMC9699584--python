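import numpy as np
import pytest

from cchr import (
    HashingNetworkSpec,
    SyntheticConfig,
    build_hashing_network,
    generate_paired_embeddings,
)


@pytest.fixture(scope="session")
def small_dataset():
    """100 clips, 5 balanced classes, separable regime."""
    return generate_paired_embeddings(SyntheticConfig(n_clips=100, seed=11))


@pytest.fixture(scope="session")
def tiny_spec():
    return HashingNetworkSpec(input_dim=512, hidden_dim=32, code_length=16, init_seed=5)


@pytest.fixture()
def tiny_nets(tiny_spec):
    from dataclasses import replace

    net_v = build_hashing_network(tiny_spec)
    net_e = build_hashing_network(replace(tiny_spec, init_seed=6))
    return net_v, net_e


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
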