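"""Metric definitions and their analytic bounds."""

import numpy as np
import pytest

from masksketch import (
    Mask,
    MaskedMinimizerScheme,
    MetricReport,
    RandomOrdering,
    Sketch,
    conservation,
    density,
    evaluate_scheme,
    gss,
    masked_minimizer_sketch,
    minimizer_sketch,
    mutate,
    random_sequence,
    w_coverage,
)

from conftest import random_instance, random_mask_pair


def test_density_examples(rng):
    assert density(Sketch([], 3), 10) == 0.0
    seq, _, k, ordering = random_instance(rng)
    sk = minimizer_sketch(seq, 1, k, ordering)
    assert density(sk, seq.n_kmers(k)) == 1.0


def test_density_lower_bound_from_window_sharing(rng):
    # consecutive windows share picks, but w windows apart cannot:
    # a minimizer sketch needs >= ceil(Lwk / w) distinct picks
    for _ in range(50):
        seq, w, k, ordering = random_instance(rng, max_L=200)
        sk = minimizer_sketch(seq, w, k, ordering)
        lwk, lk = seq.n_windows(w, k), seq.n_kmers(k)
        assert density(sk, lk) >= np.ceil(lwk / w) / lk


def test_conservation_identical_homolog_equals_density(rng):
    seq, w, k, ordering = random_instance(rng)
    scheme = MaskedMinimizerScheme(w, k, Mask.full(w), ordering)
    rep = evaluate_scheme(scheme, seq, homologs=[seq])
    assert rep.conservation == pytest.approx(rep.density)
    assert rep.gss == pytest.approx(1.0)


def test_conservation_bounded_by_density(rng):
    for _ in range(50):
        seq, w, k, ordering = random_instance(rng, max_L=200)
        hom = [mutate(seq, 0.1, seed=int(rng.integers(2**31))) for _ in range(3)]
        rep = evaluate_scheme(
            MaskedMinimizerScheme(w, k, Mask.full(w), ordering), seq, homologs=hom
        )
        assert rep.conservation <= rep.density + 1e-12


def test_conservation_empty_mask_zero(rng):
    seq, w, k, ordering = random_instance(rng)
    scheme = MaskedMinimizerScheme(w, k, Mask.empty(w), ordering)
    rep = evaluate_scheme(scheme, seq, n_homologs=2, seed=1)
    assert rep.conservation == 0.0 and rep.density == 0.0 and rep.gss == 0.0


def test_length_mismatch_rejected(rng):
    seq = random_sequence(60, seed=1)
    scheme = MaskedMinimizerScheme(4, 3, Mask.full(4), RandomOrdering(3, seed=0))
    with pytest.raises(ValueError):
        evaluate_scheme(scheme, seq, homologs=[random_sequence(59, seed=2)])


class TestCoverage:
    def test_full_mask_minimizer_covers_everything(self, rng):
        for _ in range(20):
            seq, w, k, ordering = random_instance(rng)
            sk = minimizer_sketch(seq, w, k, ordering)
            assert w_coverage(sk, seq, w, k) == 1.0

    def test_empty_sketch_zero(self, rng):
        seq, w, k, _ = random_instance(rng)
        assert w_coverage(Sketch([], k), seq, w, k) == 0.0

    def test_single_interior_pick_covers_w_windows(self):
        # window i holds k-mer indices [i, i+w-1], so an interior pick j
        # is overlapped by exactly the w windows i in [j-w+1, j]
        seq = random_sequence(100, seed=0)
        w, k = 5, 4
        lwk = seq.n_windows(w, k)
        assert w_coverage(Sketch([50], k), seq, w, k) == pytest.approx(w / lwk)

    def test_single_pick_at_origin_covers_one_window(self):
        # the edge pick j = 0 lies only in window 0
        seq = random_sequence(100, seed=0)
        w, k = 5, 4
        lwk = seq.n_windows(w, k)
        assert w_coverage(Sketch([0], k), seq, w, k) == pytest.approx(1 / lwk)


def test_gss_zero_for_empty_sketch():
    assert gss(0.0, 0.0, 0.0) == 0.0


def test_gss_in_unit_interval_randomized(rng):
    for _ in range(100):
        seq, w, k, ordering = random_instance(rng, max_L=150)
        mask = Mask(w, np.flatnonzero(rng.random(w) < 0.5))
        sk = masked_minimizer_sketch(seq, w, k, mask, ordering)
        hom = [mutate(seq, 0.05, seed=int(rng.integers(2**31)))]
        hsk = [masked_minimizer_sketch(h, w, k, mask, ordering) for h in hom]
        lk = seq.n_kmers(k)
        d, c = density(sk, lk), conservation(sk, hsk, lk)
        g = gss(d, c, w_coverage(sk, seq, w, k))
        assert 0.0 <= g <= 1.0 + 1e-12


def test_mask_monotonicity_of_density_and_conservation(rng):
    # nested masks, identical homolog draws: both metrics must be ordered
    for _ in range(100):
        seq, w, k, ordering = random_instance(rng, max_L=150)
        small, big = random_mask_pair(rng, w)
        hom = [mutate(seq, 0.05, seed=int(rng.integers(2**31)))]
        lk = seq.n_kmers(k)
        d, c = {}, {}
        for key, mask in (("small", small), ("big", big)):
            sk = masked_minimizer_sketch(seq, w, k, mask, ordering)
            hsk = [masked_minimizer_sketch(h, w, k, mask, ordering) for h in hom]
            d[key], c[key] = density(sk, lk), conservation(sk, hsk, lk)
        assert d["small"] <= d["big"]
        assert c["small"] <= c["big"]


def test_metric_report_validates_bounds():
    with pytest.raises(ValueError):
        MetricReport(density=0.1, conservation=0.2, coverage=1.0, gss=0.5,
                     n_homologs=1, substitution_rate=0.05, seed=0)
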