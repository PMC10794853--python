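"""Trainable priority / template score models (pure numpy, manual grads).

The priority model scores each k-mer from its content alone (a one-hot
MLP), so its score vector always defines a valid k-mer ordering:
identical k-mers get identical scores wherever they occur.  The template
model scores *positions* with a sinusoid of period w plus a trainable
per-residue correction; its minima recur once per window, so the sketch
it induces has density close to the minimizer optimum 1/w.  Training
pulls the priority scores toward the template at the positions that
matter, transferring the template's low density onto a content-based —
and therefore translation-robust — ordering.

Both models output in (0, 1) via a logistic squash and are evaluated in
float64, so inference is deterministic.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class PriorityModel:
    """MLP over positional n-gram features of a k-mer, output in (0, 1).

    Each k-mer is represented by the identities of its ``order``-grams at
    every position (``order=3``: k-2 positional trinucleotides).  The
    first layer is an embedding sum — mathematically a dense layer over
    the one-hot n-gram encoding, computed by gather instead of matmul —
    followed by a tanh hidden layer and a logistic output unit.

    Higher-order features make the learned score less smooth under
    single-base substitution (one substitution perturbs up to ``order``
    feature blocks), which is what lets the conservation objective
    meaningfully separate robust from fragile orderings.

    Parameters
    ----------
    k : k-mer length.
    hidden : width of the tanh hidden layer.
    order : n-gram order of the positional features (1 or 3); requires
        k >= order.
    alphabet_size : symbols per position (4 for DNA).
    seed : initialization seed.
    """

    def __init__(self, k: int, hidden: int = 128, order: int = 3,
                 alphabet_size: int = 4, seed: int = 0):
        if order < 1 or order > k:
            raise ValueError(f"order must be in [1, k], got {order}")
        self.k = k
        self.hidden = hidden
        self.order = order
        self.alphabet_size = alphabet_size
        self.n_blocks = k - order + 1
        self.n_codes = alphabet_size**order
        rng = np.random.default_rng(seed)
        self.params = {
            # E[j, c] = first-layer weights of n-gram code c at position j
            "E": rng.normal(0.0, 1.0 / np.sqrt(self.n_blocks),
                            size=(self.n_blocks, self.n_codes, hidden)),
            "b1": np.zeros(hidden),
            "W2": rng.normal(0.0, 1.0 / np.sqrt(hidden), size=hidden),
            "b2": np.zeros(()),
        }

    def encode(self, kmer_codes: np.ndarray) -> np.ndarray:
        """(n, k) int base codes -> (n, n_blocks) int n-gram codes."""
        n, k = kmer_codes.shape
        if k != self.k:
            raise ValueError(f"model is over {self.k}-mers, got {k}-mers")
        feats = np.zeros((n, self.n_blocks), dtype=np.int64)
        for d in range(self.order):
            feats = feats * self.alphabet_size + kmer_codes[:, d : d + self.n_blocks]
        return feats

    def forward(self, feats: np.ndarray) -> tuple[np.ndarray, dict]:
        e = self.params["E"]
        pre = self.params["b1"] + e[np.arange(self.n_blocks), feats].sum(axis=1)
        h = np.tanh(pre)
        # elementwise-then-reduce keeps identical rows bit-identical (a BLAS
        # matvec may round differently depending on row alignment)
        z = (h * self.params["W2"]).sum(axis=1) + self.params["b2"]
        p = _sigmoid(z)
        return p, {"feats": feats, "h": h, "p": p}

    def backward(self, cache: dict, dp: np.ndarray) -> dict:
        p, h, feats = cache["p"], cache["h"], cache["feats"]
        dz = dp * p * (1.0 - p)
        grads = {
            "W2": h.T @ dz,
            "b2": np.asarray(dz.sum()),
        }
        dh = np.outer(dz, self.params["W2"]) * (1.0 - h**2)
        grads["b1"] = dh.sum(axis=0)
        de = np.zeros_like(self.params["E"])
        for j in range(self.n_blocks):
            np.add.at(de[j], feats[:, j], dh)
        grads["E"] = de
        return grads

    def score_codes(self, kmer_codes: np.ndarray) -> np.ndarray:
        p, _ = self.forward(self.encode(kmer_codes))
        return p

    def score_vector(self, seq) -> np.ndarray:
        """Scores of all k-mers of a :class:`Sequence`."""
        return self.score_codes(seq.kmer_codes(self.k))


class TemplateModel:
    """Positional template g: N -> (0, 1) with period-w structure.

    T[m] = sigmoid(amp * cos(2*pi*(m - phase)/w) + bias + corr[m mod w]).
    With amp > 0 the minimum recurs once per period at the residue
    opposite the phase, so the induced minimizer sketch has density
    ~1/w immediately after initialization.  amp, phase, bias and the
    per-residue correction are all trainable.
    """

    def __init__(self, w: int, seed: int = 0):
        self.w = w
        rng = np.random.default_rng(seed)
        self.params = {
            "amp": np.asarray(3.0),
            "bias": np.asarray(0.0),
            # small offset avoids exact cos ties between residues
            "phase": np.asarray(0.25 + 0.01 * rng.standard_normal()),
            "corr": np.zeros(w),
        }

    def forward(self, positions: np.ndarray) -> tuple[np.ndarray, dict]:
        w = self.w
        res = positions % w
        theta = 2.0 * np.pi * (positions - self.params["phase"]) / w
        z = self.params["amp"] * np.cos(theta) + self.params["bias"] + self.params["corr"][res]
        t = _sigmoid(z)
        return t, {"theta": theta, "res": res, "t": t}

    def backward(self, cache: dict, dt: np.ndarray) -> dict:
        t, theta, res = cache["t"], cache["theta"], cache["res"]
        dz = dt * t * (1.0 - t)
        grads = {
            "amp": np.asarray((dz * np.cos(theta)).sum()),
            "bias": np.asarray(dz.sum()),
            "phase": np.asarray(
                (dz * self.params["amp"] * np.sin(theta) * (2.0 * np.pi / self.w)).sum()
            ),
            "corr": np.bincount(res, weights=dz, minlength=self.w),
        }
        return grads

    def score_positions(self, n: int, start: int = 0) -> np.ndarray:
        t, _ = self.forward(np.arange(start, start + n))
        return t


class Adam:
    """Minimal Adam optimizer over a dict of numpy parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, g in grads.items():
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g**2
            mhat = self.m[key] / (1 - b1**self.t)
            vhat = self.v[key] / (1 - b2**self.t)
            self.params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
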