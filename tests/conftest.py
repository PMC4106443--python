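"""Shared fixtures: small seeded synthetic instances."""

import numpy as np
import pytest

from crenet.simulate import SimConfig, generate_timeseries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_promoters(rng, n=20, length=200, gc=0.4):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return {
        f"g{i:03d}": "".join(rng.choice(list("ACGT"), size=length, p=p))
        for i in range(n)
    }


@pytest.fixture
def planted_network():
    """Intersection-ready noiseless three-community time series."""
    cfg = SimConfig(n_genes=60, n_communities=3, noise_sd=0.0, seed=3)
    ts, partition = generate_timeseries(cfg)
    return ts, partition
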