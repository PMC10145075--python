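import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from edvsnp import GenotypeMatrix, Locus

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_matrix(calls, chrom="Chr1", spacing=1000, start=1000):
    """GenotypeMatrix from a plain call list-of-lists, loci spaced apart."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    loci = [
        Locus(chrom, start + j * spacing, "A", "G") for j in range(L)
    ]
    return GenotypeMatrix([f"S{i + 1}" for i in range(n)], loci, calls)


def random_matrix(rng, n_samples, n_loci, miss_rate=0.1):
    calls = rng.integers(0, 3, size=(n_samples, n_loci)).astype(np.int8)
    calls[rng.random((n_samples, n_loci)) < miss_rate] = -1
    return make_matrix(calls)


@pytest.fixture
def small_matrix():
    # 4 samples x 3 loci covering all four codes
    return make_matrix(
        [
            [0, 1, 2],
            [0, 1, -1],
            [1, 2, 2],
            [2, 0, 2],
        ]
    )
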