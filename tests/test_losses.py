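"""Surrogate losses: oracle evaluation, gradients, degenerate cases."""

import numpy as np
import pytest

from masksketch import Mask
from masksketch.losses import (
    conservation_loss_grads,
    density_loss,
    density_loss_grads,
    gss_loss,
    gss_loss_grads,
)

MODES = ("softmin", "template")


def double_loop_density_loss(p, t, mask, lam, tau, mode):
    """Literal per-window, per-offset evaluation of the loss."""
    lk = len(p)
    w = mask.width
    loss = lam * sum((1 - pi) ** 2 for pi in p)
    for i in range(lk - w + 1):
        offs = list(mask)
        if not offs:
            continue
        tws = [t[i + j] for j in offs]
        if mode == "softmin":
            ex = [np.exp(-tw / tau) for tw in tws]
            weights = [e / sum(ex) for e in ex]
        else:
            weights = tws
        for j, wt in zip(offs, weights):
            loss += wt * (p[i + j] - t[i + j]) ** 2
    return loss


@pytest.mark.parametrize("mode", MODES)
class TestDensityLoss:
    def test_zero_when_both_all_ones(self, mode):
        p = t = np.ones(10)
        for mask in (Mask.full(4), Mask(4, [1, 3]), Mask.empty(4)):
            assert density_loss(p, t, mask, 1.0, mode=mode) == pytest.approx(0.0)

    def test_empty_mask_regularizer_only(self, rng, mode):
        p, t = rng.random(8), rng.random(8)
        lam = 0.6
        expected = lam * np.sum((1 - p) ** 2)
        assert density_loss(p, t, Mask.empty(3), lam, mode=mode) == pytest.approx(expected)

    def test_matches_double_loop_oracle(self, rng, mode):
        for _ in range(20):
            lk = int(rng.integers(6, 15))
            w = int(rng.integers(2, min(5, lk)))
            offs = np.flatnonzero(rng.random(w) < 0.6)
            mask = Mask(w, offs)
            p, t = rng.random(lk), rng.random(lk)
            lam, tau = float(rng.random()), 0.2
            got = density_loss(p, t, mask, lam, tau, mode)
            want = double_loop_density_loss(p, t, mask, lam, tau, mode)
            assert got == pytest.approx(want, rel=1e-12)

    def test_gradients_match_finite_differences(self, rng, mode):
        p, t = rng.random(12), rng.random(12)
        mask = Mask(4, [0, 2, 3])
        lam, tau, eps = 0.7, 0.15, 1e-6
        _, gp, gt = density_loss_grads(p, t, mask, lam, tau, mode)
        for vec, grad, which in ((p, gp, "p"), (t, gt, "t")):
            for i in range(len(vec)):
                hi, lo = vec.copy(), vec.copy()
                hi[i] += eps
                lo[i] -= eps
                if which == "p":
                    num = (density_loss(hi, t, mask, lam, tau, mode)
                           - density_loss(lo, t, mask, lam, tau, mode)) / (2 * eps)
                else:
                    num = (density_loss(p, hi, mask, lam, tau, mode)
                           - density_loss(p, lo, mask, lam, tau, mode)) / (2 * eps)
                assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_nonnegative(self, rng, mode):
        for _ in range(50):
            p, t = rng.random(10), rng.random(10)
            assert density_loss(p, t, Mask(3, [0, 2]), 0.5, mode=mode) >= 0.0

    def test_length_mismatch(self, mode):
        with pytest.raises(ValueError):
            density_loss(np.ones(5), np.ones(6), Mask.full(2), mode=mode)


class TestGssLoss:
    def test_lambda_con_zero_equals_density_loss(self, rng):
        p, t = rng.random(10), rng.random(10)
        homs = [rng.random(10)]
        mask = Mask(3, [1])
        assert gss_loss(p, homs, t, mask, 1.0, lambda_con=0.0) == \
            pytest.approx(density_loss(p, t, mask, 1.0))

    def test_identical_homologs_scale_loss(self, rng):
        p, t = rng.random(10), rng.random(10)
        mask = Mask(3, [0, 2])
        lam_c = 1.5
        got = gss_loss(p, [p.copy(), p.copy()], t, mask, 1.0, lambda_con=lam_c)
        assert got == pytest.approx((1 + lam_c) * density_loss(p, t, mask, 1.0))

    def test_small_instance_matches_formula(self, rng):
        p, t = rng.random(8), rng.random(8)
        homs = [rng.random(8), rng.random(8)]
        mask = Mask(3, [1, 2])
        lam, lam_c = 0.8, 2.0
        want = density_loss(p, t, mask, lam) + lam_c / 2 * sum(
            density_loss(h, t, mask, lam) for h in homs
        )
        assert gss_loss(p, homs, t, mask, lam, lam_c) == pytest.approx(want)

    def test_no_homologs_with_positive_lambda_con(self, rng):
        with pytest.raises(ValueError):
            gss_loss_grads(rng.random(6), [], rng.random(6), Mask.full(2))

    def test_homolog_gradients_match_finite_differences(self, rng):
        p, t = rng.random(9), rng.random(9)
        h = rng.random(9)
        mask = Mask(3, [0, 1])
        eps = 1e-6
        _, _, ghoms, _ = gss_loss_grads(p, [h], t, mask, 1.0, 1.3)
        for i in range(len(h)):
            hi, lo = h.copy(), h.copy()
            hi[i] += eps
            lo[i] -= eps
            num = (gss_loss(p, [hi], t, mask, 1.0, 1.3)
                   - gss_loss(p, [lo], t, mask, 1.0, 1.3)) / (2 * eps)
            assert ghoms[0][i] == pytest.approx(num, rel=1e-4, abs=1e-8)


def test_conservation_loss_is_mean_of_homolog_terms(rng):
    t = rng.random(10)
    homs = [rng.random(10) for _ in range(3)]
    mask = Mask(4, [0, 3])
    loss, _, _ = conservation_loss_grads(homs, t, mask, 0.5)
    want = np.mean([density_loss(h, t, mask, 0.5) for h in homs])
    assert loss == pytest.approx(want)
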