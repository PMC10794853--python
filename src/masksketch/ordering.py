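"""k-mer orderings: scoring functions f_pi mapping k-mers to [0, 1].

An ordering induces the precedence ``kappa < kappa'  iff  f(kappa) <
f(kappa')``; k-mers with equal scores are ranked by their order of
appearance in the window (leftmost wins).  Orderings must be
content-deterministic: identical k-mer strings always score identically,
wherever they occur.
"""

from __future__ import annotations

import numpy as np

from .sequence import Sequence

__all__ = [
    "Ordering",
    "RandomOrdering",
    "LexicographicOrdering",
    "VectorOrdering",
]


class Ordering:
    """Base class.  Subclasses implement :meth:`score_codes`.

    Attributes
    ----------
    k:
        Length of the substrings being ordered (k-mers, or s-mers when an
        ordering drives a syncmer scheme).
    """

    tiebreak = "leftmost-in-window"

    def __init__(self, k: int):
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        self.k = k

    def score_codes(self, codes: np.ndarray) -> np.ndarray:
        """Scores in [0, 1] for an (n, k) int array of base codes."""
        raise NotImplementedError

    def score(self, kmer: str) -> float:
        """Score of one k-mer string."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {kmer!r}")
        codes = Sequence(kmer).codes[None, :]
        return float(self.score_codes(codes)[0])

    def score_vector(self, seq: Sequence) -> np.ndarray:
        """Scores of every k-mer of ``seq``, shape (Lk,)."""
        return self.score_codes(seq.kmer_codes(self.k)).astype(np.float64)


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Bijective 64-bit finalizer (splitmix64); vectorized, uint64 in/out."""
    with np.errstate(over="ignore"):
        x = x + np.uint64(0x9E3779B97F4A7C15)
        x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        return x ^ (x >> np.uint64(31))


class RandomOrdering(Ordering):
    """A seeded pseudo-random ordering, effectively one-to-one.

    Each k-mer's base-4 code is mixed through splitmix64 with a
    seed-derived key, giving i.i.d.-looking scores in [0, 1).  Distinct
    k-mers collide with probability ~2^-64, so for test-sized inputs this
    behaves as a random one-to-one ordering.
    """

    def __init__(self, k: int, seed: int = 0, alphabet_size: int = 4):
        super().__init__(k)
        self.seed = int(seed)
        self.alphabet_size = alphabet_size
        self._key = _splitmix64(np.uint64(np.uint64(self.seed) & np.uint64(2**63 - 1)))

    def score_codes(self, codes: np.ndarray) -> np.ndarray:
        base = np.uint64(self.alphabet_size)
        h = np.zeros(codes.shape[0], dtype=np.uint64)
        with np.errstate(over="ignore"):
            for j in range(codes.shape[1]):
                h = h * np.uint64(0x100000001B3) + codes[:, j].astype(np.uint64)
                h = h * base + np.uint64(1)
            h = _splitmix64(h ^ self._key)
        return h.astype(np.float64) / 2.0**64


class LexicographicOrdering(Ordering):
    """Scores k-mers by their base-4 rank: score = code / 4^k.

    Exact (collision-free) for k <= 26, where 4^k fits in a float64
    mantissa.
    """

    def __init__(self, k: int, alphabet_size: int = 4):
        super().__init__(k)
        if alphabet_size**k > 2**53:
            raise ValueError(f"lexicographic ordering needs {alphabet_size}^k <= 2^53")
        self.alphabet_size = alphabet_size

    def score_codes(self, codes: np.ndarray) -> np.ndarray:
        n = self.alphabet_size
        val = np.zeros(codes.shape[0], dtype=np.float64)
        for j in range(codes.shape[1]):
            val = val * n + codes[:, j]
        return val / float(n**self.k)


class VectorOrdering(Ordering):
    """An ordering backed by an explicit {k-mer string: score} table.

    Used to wrap trained priority models' score tables and in tests where
    a hand-set ordering is needed.  Unknown k-mers raise, keeping the
    table authoritative.
    """

    def __init__(self, k: int, table: dict[str, float]):
        super().__init__(k)
        for km, sc in table.items():
            if len(km) != k:
                raise ValueError(f"table key {km!r} is not a {k}-mer")
            if not 0.0 <= sc <= 1.0:
                raise ValueError(f"score {sc} for {km!r} outside [0, 1]")
        self.table = dict(table)

    def score(self, kmer: str) -> float:
        try:
            return float(self.table[kmer])
        except KeyError:
            raise KeyError(f"k-mer {kmer!r} not in ordering table") from None

    def score_codes(self, codes: np.ndarray) -> np.ndarray:
        from .sequence import DNA

        out = np.empty(codes.shape[0], dtype=np.float64)
        for i, row in enumerate(codes):
            out[i] = self.score("".join(DNA[c] for c in row))
        return out
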