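import numpy as np
import pytest

import delimetrics as dm


@pytest.fixture
def abcd():
    """The four named partitions of {a,b,c,d} used throughout: coarse to fine."""
    return {
        "one_block": dm.build_partition([["a", "b", "c", "d"]], label="one_block"),
        "halves": dm.build_partition([["a", "b"], ["c", "d"]], label="halves"),
        "a_b_cd": dm.build_partition([["a"], ["b"], ["c", "d"]], label="a_b_cd"),
        "singletons": dm.build_partition(
            [["a"], ["b"], ["c"], ["d"]], label="singletons"
        ),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_pair(rng, n_max=30, model="uniform", alpha=1.5):
    """A seeded pair of comparable random partitions."""
    n = int(rng.integers(2, n_max + 1))
    u = dm.random_partition(n, rng, model=model, crp_alpha=alpha)
    v = dm.random_partition(n, rng, model=model, crp_alpha=alpha)
    return u, v
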