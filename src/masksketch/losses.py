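"""Differentiable surrogate losses for masked-minimizer density and GSS.

The density loss measures a regularized, window-aggregated squared
distance between the priority scores P and the template scores T:

    L_DM(P, T; v) = lambda * ||1 - P||^2
                    + sum_i sum_{j in v} weight(i, j) * (P[i+j] - T[i+j])^2

with one inner sum per (w,k)-window i over the qualifying offsets v.
Two weightings are provided:

* ``"softmin"`` (default): weight(i, .) is a softmin over the window's
  qualifying template values (temperature ``tau``).  Weight concentrates
  on the position most likely to be the window's sampled minimizer, so
  minimizing the loss pulls P down to T exactly at the template minima
  while the regularizer pushes every other score toward 1 — a smooth
  surrogate for the masked-minimizer sampling rule.
* ``"template"``: weight(i, j) = T[i+j], a simpler weighting in which a
  position's weight is its raw template value.

The GSS loss adds a conservation term: the mean density loss of the
priority scores of n substitution-mutated homologs against the same
template, scaled by ``lambda_con``.  Driving homolog scores toward the
same template concentrates them around P, so the sketch tends to
survive mutation.

All functions return the loss together with closed-form gradients with
respect to the P and T score vectors; model-parameter gradients are
obtained by chaining through the models' ``backward``.
"""

from __future__ import annotations

import numpy as np

from .mask import Mask

__all__ = ["density_loss", "density_loss_grads", "gss_loss", "gss_loss_grads"]


def _window_terms(p: np.ndarray, t: np.ndarray, mask: Mask, tau: float, mode: str):
    """Windowed views P[i+j], T[i+j] for j in v, plus weights A."""
    lk = len(p)
    w = mask.width
    lwk = lk - w + 1
    if lwk < 1:
        raise ValueError(f"score vector of length {lk} has no window of {w}")
    v = np.asarray(mask.offsets, dtype=np.int64)
    idx = np.arange(lwk, dtype=np.int64)[:, None] + v[None, :]
    pw, tw = p[idx], t[idx]
    if mode == "softmin":
        a = np.exp(-(tw - tw.min(axis=1, keepdims=True)) / tau)
        a /= a.sum(axis=1, keepdims=True)
    elif mode == "template":
        a = tw
    else:
        raise ValueError(f"unknown weight mode {mode!r}")
    return idx, pw, tw, a


def density_loss_grads(
    p: np.ndarray,
    t: np.ndarray,
    mask: Mask,
    lambda_reg: float = 1.0,
    tau: float = 0.1,
    mode: str = "softmin",
) -> tuple[float, np.ndarray, np.ndarray]:
    """L_DM and its gradients w.r.t. the score vectors P and T."""
    p = np.asarray(p, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"P and T lengths differ: {p.shape} vs {t.shape}")
    loss = lambda_reg * float(((1.0 - p) ** 2).sum())
    gp = -2.0 * lambda_reg * (1.0 - p)
    gt = np.zeros_like(t)
    if len(mask) == 0:
        return loss, gp, gt

    idx, pw, tw, a = _window_terms(p, t, mask, tau, mode)
    d = pw - tw
    f = d**2
    loss += float((a * f).sum())
    gpw = 2.0 * a * d
    if mode == "softmin":
        # dA/dT through the softmin plus the direct -2*A*D term
        row_mean = (a * f).sum(axis=1, keepdims=True)
        gtw = -2.0 * a * d - (a / tau) * (f - row_mean)
    else:  # template weights: d(T * D^2)/dT = D^2 - 2*T*D
        gtw = f - 2.0 * tw * d
    np.add.at(gp, idx, gpw)
    np.add.at(gt, idx, gtw)
    return loss, gp, gt


def density_loss(p, t, mask, lambda_reg: float = 1.0, tau: float = 0.1,
                 mode: str = "softmin") -> float:
    """L_DM value only."""
    return density_loss_grads(p, t, mask, lambda_reg, tau, mode)[0]


def gss_loss_grads(
    p_ref: np.ndarray,
    p_homologs: list[np.ndarray],
    t: np.ndarray,
    mask: Mask,
    lambda_reg: float = 1.0,
    lambda_con: float = 1.0,
    tau: float = 0.1,
    mode: str = "softmin",
) -> tuple[float, np.ndarray, list[np.ndarray], np.ndarray]:
    """L_gss = L_DM(P, T) + lambda_con * mean_i L_DM(P(S'_i), T)."""
    if lambda_con > 0 and len(p_homologs) == 0:
        raise ValueError("lambda_con > 0 requires at least one homolog score vector")
    loss, gp, gt = density_loss_grads(p_ref, t, mask, lambda_reg, tau, mode)
    g_homs: list[np.ndarray] = []
    n = len(p_homologs)
    for ph in p_homologs:
        li, gpi, gti = density_loss_grads(ph, t, mask, lambda_reg, tau, mode)
        scale = lambda_con / n
        loss += scale * li
        g_homs.append(scale * gpi)
        gt += scale * gti
    return loss, gp, g_homs, gt


def gss_loss(p_ref, p_homologs, t, mask, lambda_reg: float = 1.0,
             lambda_con: float = 1.0, tau: float = 0.1, mode: str = "softmin") -> float:
    """L_gss value only."""
    return gss_loss_grads(p_ref, p_homologs, t, mask, lambda_reg, lambda_con, tau, mode)[0]


def conservation_loss_grads(p_homologs, t, mask, lambda_reg=1.0, tau=0.1,
                            mode="softmin"):
    """L_con = mean_i L_DM(P(S'_i), T): the homolog term alone."""
    if len(p_homologs) == 0:
        raise ValueError("need at least one homolog score vector")
    n = len(p_homologs)
    loss = 0.0
    g_homs = []
    gt = np.zeros_like(np.asarray(t, dtype=np.float64))
    for ph in p_homologs:
        li, gpi, gti = density_loss_grads(ph, t, mask, lambda_reg, tau, mode)
        loss += li / n
        g_homs.append(gpi / n)
        gt += gti / n
    return loss, g_homs, gt
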