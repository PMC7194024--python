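"""Shared fixtures: tiny genotype datasets built in memory."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from conngen.io import make_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_dataset():
    """3 samples x 4 SNPs on two chromosomes, one missing call."""
    calls = np.array(
        [
            [2, 1, 0, 1],
            [1, -1, 2, 0],
            [0, 0, 1, 2],
        ],
        dtype=np.int8,
    )
    return make_dataset(
        calls,
        pos=[1000, 2000, 1000, 5000],
        chrom=["1", "1", "2", "2"],
        populations=["P1", "P1", "P2"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dataset(rng, n=20, m=40, missing_rate=0.0, chrom=None):
    """HWE-ish random dataset helper used across test modules."""
    p = rng.uniform(0.1, 0.5, size=m)
    calls = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    if missing_rate:
        calls[rng.random((n, m)) < missing_rate] = -1
    return make_dataset(calls, pos=rng.choice(np.arange(1, 10 * m), m, replace=False) * 100,
                        chrom=chrom)
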