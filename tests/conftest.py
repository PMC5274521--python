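import numpy as np
import pytest

from tecaller import (ReferenceGenome, RunConfig, TEFamily, TELibrary,
                      random_genome, rice_like_library)
from tecaller.io_formats import decode_seq


def rand_seq(rng, n):
    return decode_seq(rng.integers(0, 4, size=n).astype(np.uint8))


@pytest.fixture(scope="session")
def cfg():
    return RunConfig()


@pytest.fixture(scope="session")
def fixture_library():
    return rice_like_library()


@pytest.fixture(scope="session")
def small_library():
    """Three short synthetic families — small enough for brute-force oracles."""
    rng = np.random.default_rng(42)
    return TELibrary([
        TEFamily("alpha", rand_seq(rng, 500), 3),
        TEFamily("beta", rand_seq(rng, 800), 5),
        TEFamily("gamma", rand_seq(rng, 300), 2),
    ])


@pytest.fixture(scope="session")
def small_genome():
    return random_genome(60_000, seed=7, chrom="chrA")
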