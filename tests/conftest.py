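import numpy as np
import pytest
from hypothesis import settings

import monodi as m

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_model():
    """Ten genes on one 100 kb chromosome."""
    return m.make_genome(1, 100_000, 10, seed=1)


@pytest.fixture(scope="session")
def class_model():
    """Twenty genes split into constant and down classes."""
    return m.make_genome(1, 150_000, 20, seed=5,
                         class_counts={"constant": 10, "down": 10})


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_fragments(rng, n, chrom_len=1000, kind="mono", n_chroms=1):
    chroms = np.array([f"c{i}" for i in rng.integers(0, n_chroms, n)], dtype=object)
    starts = rng.integers(0, chrom_len - 2, n)
    lengths = rng.integers(1, 60, n)
    ends = np.minimum(starts + lengths, chrom_len)
    return m.FragmentSet(chroms, starts, ends, kind=kind)
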