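import numpy as np
import pytest

from masksketch import RandomOrdering, Sequence, random_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_instance(rng, max_L=300, max_w=12, max_k=12):
    """A random (seq, w, k, ordering) tuple with a feasible geometry."""
    w = int(rng.integers(1, max_w + 1))
    k = int(rng.integers(1, max_k + 1))
    wk = w + k - 1
    L = int(rng.integers(wk, max(wk + 1, max_L)))
    seq = random_sequence(L, seed=int(rng.integers(2**31)))
    ordering = RandomOrdering(k, seed=int(rng.integers(2**31)))
    return seq, w, k, ordering


def random_mask_pair(rng, width):
    """Two nested masks v ⊆ v' over [0, width-1]."""
    big = np.flatnonzero(rng.random(width) < 0.7)
    if len(big) == 0:
        big = np.array([int(rng.integers(width))])
    keep = rng.random(len(big)) < 0.6
    small = big[keep]
    from masksketch import Mask

    return Mask(width, small), Mask(width, big)
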