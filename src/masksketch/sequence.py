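"""Immutable DNA/arbitrary-alphabet sequences with k-mer bookkeeping.

A :class:`Sequence` wraps an uppercase string over a finite alphabet
(default ``ACGT``) and exposes the derived counts used throughout the
package: ``Lk = L - k + 1`` k-mers, window length ``wk = w + k - 1`` and
``Lwk = L - wk + 1`` (w,k)-windows.  All coordinates are 0-based.
"""

from __future__ import annotations

from functools import cached_property

import numpy as np

DNA = "ACGT"


class SequenceError(ValueError):
    """Raised for malformed sequences (empty, illegal symbols)."""


class Sequence:
    """An immutable uppercase sequence over a finite alphabet.

    Parameters
    ----------
    symbols:
        The sequence string; lowercase input is normalized to uppercase.
    alphabet:
        Allowed symbols.  The default is the DNA alphabet ``ACGT``.
    n_policy:
        How to treat symbols outside the alphabet (typically ``N``):
        ``"reject"`` (default) raises :class:`SequenceError` naming the
        first offending offset.  Splitting at N-runs is handled at the
        I/O layer, not here.
    """

    __slots__ = ("symbols", "alphabet", "__dict__")

    def __init__(self, symbols: str, alphabet: str = DNA, n_policy: str = "reject"):
        if n_policy != "reject":
            raise ValueError(f"unknown n_policy: {n_policy!r}")
        symbols = symbols.upper()
        if len(symbols) == 0:
            raise SequenceError("empty sequence (L must be >= 1)")
        allowed = set(alphabet)
        for off, ch in enumerate(symbols):
            if ch not in allowed:
                raise SequenceError(
                    f"illegal symbol {ch!r} at offset {off} "
                    f"(alphabet is {alphabet!r})"
                )
        self.symbols = symbols
        self.alphabet = alphabet

    @property
    def L(self) -> int:
        return len(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return self.symbols

    def __repr__(self) -> str:
        head = self.symbols if self.L <= 40 else self.symbols[:37] + "..."
        return f"Sequence({head!r}, L={self.L})"

    def __eq__(self, other) -> bool:
        return isinstance(other, Sequence) and self.symbols == other.symbols

    def __hash__(self) -> int:
        return hash(self.symbols)

    @cached_property
    def codes(self) -> np.ndarray:
        """Per-position integer codes (index into the alphabet), int8."""
        lut = np.full(256, -1, dtype=np.int8)
        for i, ch in enumerate(self.alphabet):
            lut[ord(ch)] = i
        return lut[np.frombuffer(self.symbols.encode("ascii"), dtype=np.uint8)]

    # -- derived counts -------------------------------------------------

    def n_kmers(self, k: int) -> int:
        """Lk = L - k + 1; raises if no k-mer fits."""
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        lk = self.L - k + 1
        if lk < 1:
            raise SequenceError(f"sequence of length {self.L} has no {k}-mer")
        return lk

    def n_windows(self, w: int, k: int) -> int:
        """Lwk = L - (w + k - 1) + 1; raises if no (w,k)-window fits."""
        if w < 1:
            raise ValueError(f"w must be >= 1, got {w}")
        lwk = self.L - (w + k - 1) + 1
        if lwk < 1:
            raise SequenceError(
                f"sequence of length {self.L} has no ({w},{k})-window "
                f"(needs L >= {w + k - 1})"
            )
        return lwk

    def kmer(self, i: int, k: int) -> str:
        """The i-th k-mer (0-based start index)."""
        if not 0 <= i <= self.L - k:
            raise IndexError(f"k-mer start {i} out of [0, {self.L - k}]")
        return self.symbols[i : i + k]

    def kmer_codes(self, k: int) -> np.ndarray:
        """(Lk, k) int8 array of per-base codes for every k-mer (a view)."""
        lk = self.n_kmers(k)
        return np.lib.stride_tricks.sliding_window_view(self.codes, k)[:lk]


def window_length(w: int, k: int) -> int:
    """wk = w + k - 1, the base length of a (w,k)-window."""
    return w + k - 1
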