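import numpy as np
import pytest

from stickerslab.model import ForceField, SystemConfiguration


@pytest.fixture(scope="session")
def ff():
    return ForceField()


def make_random_config(n_chain=2, chain_len=5, box=20.0, seed=0, spread=4.0):
    """Small random multi-chain configuration with alternating sticker types."""
    rng = np.random.default_rng(seed)
    n = n_chain * chain_len
    types = np.array([(i % 2) for i in range(n)], dtype=np.int8)
    bonds = []
    chain_id = np.empty(n, dtype=np.int64)
    for c in range(n_chain):
        base = c * chain_len
        chain_id[base:base + chain_len] = c
        for i in range(chain_len - 1):
            bonds.append((base + i, base + i + 1))
    pos = np.empty((n, 3))
    for c in range(n_chain):
        base = c * chain_len
        pos[base] = rng.uniform(0, box, 3)
        for i in range(1, chain_len):
            step = rng.normal(size=3)
            step *= 0.9 / np.linalg.norm(step)
            pos[base + i] = pos[base + i - 1] + step
    pos += rng.uniform(-spread / 10, spread / 10, size=pos.shape)
    return SystemConfiguration(
        positions=pos,
        box=np.array([box, box, box]),
        types=types,
        bonds=np.asarray(bonds, dtype=np.int64),
        chain_id=chain_id,
    )


@pytest.fixture
def random_config():
    return make_random_config()
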