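"""Sampling-scheme semantics: tie-breaking, reductions, monotonicity."""

import numpy as np
import pytest

from masksketch import (
    LexicographicOrdering,
    Mask,
    RandomOrdering,
    Sequence,
    index_selector,
    masked_minimizer_sketch,
    minimizer_sketch,
    open_syncmer_sketch,
    parameterized_syncmer_sketch,
    random_sequence,
)
from masksketch.oracle import naive_masked_minimizer, naive_parameterized_syncmer

from conftest import random_instance, random_mask_pair


class TestIndexSelector:
    def test_single_candidate_window(self, rng):
        seq, w, k, ordering = random_instance(rng)
        assert index_selector(seq, ordering, 0, 1) == 0

    def test_all_equal_ties_leftmost(self):
        seq = Sequence("AAAA")
        assert index_selector(seq, RandomOrdering(1, seed=5), 0, 4) == 0

    def test_lexicographic_scan(self):
        # candidates AC, CG, GT, TA: AC is lexicographically least
        seq = Sequence("ACGTAC")
        assert index_selector(seq, LexicographicOrdering(2), 0, 4) == 0

    def test_out_of_range(self):
        seq = Sequence("ACGTAC")
        with pytest.raises(IndexError):
            index_selector(seq, LexicographicOrdering(2), 3, 4)


class TestMinimizer:
    def test_w1_selects_every_kmer(self, rng):
        seq, _, k, ordering = random_instance(rng)
        sk = minimizer_sketch(seq, 1, k, ordering)
        assert list(sk.indices) == list(range(seq.n_kmers(k)))

    @pytest.mark.parametrize("w,k", [(3, 2), (4, 3), (2, 5)])
    def test_homopolymer_leftmost_per_window(self, w, k):
        seq = Sequence("A" * 12)
        sk = minimizer_sketch(seq, w, k, RandomOrdering(k, seed=1))
        # all k-mers tie, so window i picks offset 0, i.e. index i
        assert list(sk.indices) == list(range(seq.n_windows(w, k)))

    def test_window_guarantee(self, rng):
        for _ in range(30):
            seq, w, k, ordering = random_instance(rng)
            sk = minimizer_sketch(seq, w, k, ordering)
            idx = sk.indices
            for i in range(seq.n_windows(w, k)):
                assert np.any((idx >= i) & (idx <= i + w - 1))

    def test_too_short_sequence_raises(self):
        with pytest.raises(Exception):
            minimizer_sketch(Sequence("ACGT"), 4, 3, RandomOrdering(3))


class TestMaskedMinimizer:
    def test_full_mask_equals_minimizer(self, rng):
        for _ in range(30):
            seq, w, k, ordering = random_instance(rng)
            assert masked_minimizer_sketch(seq, w, k, Mask.full(w), ordering) == \
                minimizer_sketch(seq, w, k, ordering)

    def test_empty_mask_empty_sketch(self, rng):
        seq, w, k, ordering = random_instance(rng)
        assert len(masked_minimizer_sketch(seq, w, k, Mask.empty(w), ordering)) == 0

    def test_wrong_mask_width(self):
        seq = random_sequence(50, seed=0)
        with pytest.raises(ValueError):
            masked_minimizer_sketch(seq, 5, 3, Mask.full(4), RandomOrdering(3))

    def test_matches_naive_oracle_single_offset(self, rng):
        seq = random_sequence(60, seed=int(rng.integers(2**31)))
        ordering = RandomOrdering(4, seed=int(rng.integers(2**31)))
        mask = Mask.single(6, 3)
        assert masked_minimizer_sketch(seq, 6, 4, mask, ordering) == \
            naive_masked_minimizer(seq, 6, 4, mask, ordering)

    def test_subset_monotonicity(self, rng):
        for _ in range(100):
            seq, w, k, ordering = random_instance(rng, max_L=150)
            small, big = random_mask_pair(rng, w)
            sk_small = masked_minimizer_sketch(seq, w, k, small, ordering)
            sk_big = masked_minimizer_sketch(seq, w, k, big, ordering)
            assert sk_small.issubset(sk_big)


class TestSyncmers:
    def test_open_equals_single_offset_parameterized(self, rng):
        for _ in range(20):
            seq = random_sequence(80, seed=int(rng.integers(2**31)))
            k, s = 8, 4
            ks = k - s + 1
            ordering = RandomOrdering(s, seed=int(rng.integers(2**31)))
            t = int(rng.integers(ks))
            assert open_syncmer_sketch(seq, k, s, t, ordering) == \
                parameterized_syncmer_sketch(seq, k, s, Mask.single(ks, t), ordering)

    def test_t0_homopolymer_selects_all(self):
        seq = Sequence("A" * 20)
        sk = open_syncmer_sketch(seq, 6, 3, 0, RandomOrdering(3, seed=9))
        assert list(sk.indices) == list(range(seq.n_kmers(6)))

    def test_matches_naive_oracle(self, rng):
        seq = random_sequence(40, seed=int(rng.integers(2**31)))
        ordering = RandomOrdering(4, seed=int(rng.integers(2**31)))
        assert open_syncmer_sketch(seq, 8, 4, 2, ordering) == \
            naive_parameterized_syncmer(seq, 8, 4, Mask.single(5, 2), ordering)

    def test_closed_is_union_of_extreme_open(self, rng):
        seq = random_sequence(60, seed=int(rng.integers(2**31)))
        k, s = 10, 5
        ks = k - s + 1
        ordering = RandomOrdering(s, seed=int(rng.integers(2**31)))
        closed = parameterized_syncmer_sketch(seq, k, s, Mask.closed(ks), ordering)
        lo = open_syncmer_sketch(seq, k, s, 0, ordering)
        hi = open_syncmer_sketch(seq, k, s, ks - 1, ordering)
        union = np.union1d(lo.indices, hi.indices)
        np.testing.assert_array_equal(closed.indices, union)

    def test_full_mask_selects_every_kmer(self, rng):
        seq = random_sequence(50, seed=3)
        ordering = RandomOrdering(3, seed=4)
        sk = parameterized_syncmer_sketch(seq, 7, 3, Mask.full(5), ordering)
        assert list(sk.indices) == list(range(seq.n_kmers(7)))

    def test_parameter_errors(self):
        seq = random_sequence(50, seed=0)
        with pytest.raises(ValueError):
            open_syncmer_sketch(seq, 4, 4, 0, RandomOrdering(4))
        with pytest.raises(ValueError):
            open_syncmer_sketch(seq, 8, 4, 5, RandomOrdering(4))  # t > ks-1


def test_determinism(rng):
    seq, w, k, _ = random_instance(rng)
    a = minimizer_sketch(seq, w, k, RandomOrdering(k, seed=42))
    b = minimizer_sketch(Sequence(seq.symbols), w, k, RandomOrdering(k, seed=42))
    assert a == b
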