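"""The four k-mer sampling schemes.

Minimizers (one lowest-scoring k-mer per (w,k)-window), open syncmers
(k-mers whose minimal constituent s-mer sits at a fixed offset t),
parameterized syncmers (the offset may lie anywhere in a subset v), and
masked minimizers (a window's minimizer is kept only if its in-window
offset lies in v).  With the full mask a masked minimizer is exactly a
minimizer; with |v| = 1 a parameterized syncmer is an open syncmer.

All schemes are driven by a score vector over k-mers (or s-mers) and
break score ties by leftmost position in the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mask import Mask
from .ordering import Ordering
from .sequence import Sequence


@dataclass(frozen=True)
class Sketch:
    """A sorted set of selected k-mer start indices (0-based)."""

    indices: np.ndarray  # int64, strictly increasing, unique
    k: int

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.int64)
        idx = np.unique(idx)
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Sketch)
            and self.k == other.k
            and np.array_equal(self.indices, other.indices)
        )

    def issubset(self, other: "Sketch") -> bool:
        return len(np.setdiff1d(self.indices, other.indices, assume_unique=True)) == 0

    def intersection_size(self, other: "Sketch") -> int:
        return len(np.intersect1d(self.indices, other.indices, assume_unique=True))


# ---------------------------------------------------------------------
# index selector and score-vector kernels
# ---------------------------------------------------------------------

def index_selector(seq: Sequence, ordering: Ordering, a: int, b: int) -> int:
    """argmin over j in [0, b-1] of score(k-mer at a+j); leftmost ties.

    ``a`` is a 0-based k-mer start index and ``b`` the window width in
    k-mers.
    """
    lk = seq.n_kmers(ordering.k)
    if b < 1 or a < 0 or a + b - 1 > lk - 1:
        raise IndexError(f"window [{a}, {a + b - 1}] outside k-mer range [0, {lk - 1}]")
    scores = ordering.score_codes(seq.kmer_codes(ordering.k)[a : a + b])
    return int(np.argmin(scores))  # np.argmin returns the first minimum


def sketch_from_scores(scores: np.ndarray, w: int, mask: Mask, k: int) -> Sketch:
    """Masked-minimizer sketch from a precomputed k-mer score vector.

    This positional kernel is shared by the ordering-driven schemes and
    by training, where scores come straight from a priority model.
    """
    if mask.width != w:
        raise ValueError(f"mask width {mask.width} != window size {w}")
    lk = len(scores)
    lwk = lk - w + 1
    if lwk < 1:
        raise ValueError(f"{lk} k-mers cannot form a window of {w}")
    windows = np.lib.stride_tricks.sliding_window_view(scores, w)
    m = np.argmin(windows, axis=1)  # leftmost tie-break
    keep = mask.indicator()[m]
    picks = np.arange(lwk, dtype=np.int64)[keep] + m[keep]
    return Sketch(np.unique(picks), k)


def syncmer_offsets(s_scores: np.ndarray, ks: int) -> np.ndarray:
    """Per-k-mer offset of the minimal constituent s-mer (leftmost ties)."""
    windows = np.lib.stride_tricks.sliding_window_view(s_scores, ks)
    return np.argmin(windows, axis=1)


# ---------------------------------------------------------------------
# scheme operations
# ---------------------------------------------------------------------

def minimizer_sketch(seq: Sequence, w: int, k: int, ordering: Ordering) -> Sketch:
    """Plain minimizers: Eq.-style {i + m(i, w)} over all windows."""
    return masked_minimizer_sketch(seq, w, k, Mask.full(w), ordering)

def masked_minimizer_sketch(
    seq: Sequence, w: int, k: int, mask: Mask, ordering: Ordering
) -> Sketch:
    """Minimizers whose in-window offset lies in the mask v."""
    if k < 1 or w < 1:
        raise ValueError(f"w and k must be >= 1, got w={w}, k={k}")
    if ordering.k != k:
        raise ValueError(f"ordering is over {ordering.k}-mers, scheme needs {k}-mers")
    seq.n_windows(w, k)  # validates L >= w + k - 1
    scores = ordering.score_vector(seq)
    return sketch_from_scores(scores, w, mask, k)

def open_syncmer_sketch(
    seq: Sequence, k: int, s: int, t: int, ordering: Ordering
) -> Sketch:
    """k-mers whose minimal s-mer sits exactly at offset t in [0, ks-1]."""
    ks = k - s + 1
    if not 0 <= t <= ks - 1:
        raise ValueError(f"offset t={t} outside [0, {ks - 1}]")
    return parameterized_syncmer_sketch(seq, k, s, Mask.single(ks, t), ordering)

def parameterized_syncmer_sketch(
    seq: Sequence, k: int, s: int, mask: Mask, ordering: Ordering
) -> Sketch:
    """k-mers whose minimal s-mer offset lies in v subset of [0, ks-1]."""
    if not 1 <= s < k:
        raise ValueError(f"need 1 <= s < k, got s={s}, k={k}")
    ks = k - s + 1
    if mask.width != ks:
        raise ValueError(f"mask width {mask.width} != ks = {ks}")
    if ordering.k != s:
        raise ValueError(f"ordering is over {ordering.k}-mers, scheme needs {s}-mers")
    lk = seq.n_kmers(k)
    s_scores = ordering.score_vector(seq)
    m = syncmer_offsets(s_scores, ks)
    assert len(m) == lk
    picks = np.arange(lk, dtype=np.int64)[mask.indicator()[m]]
    return Sketch(picks, k)


# ---------------------------------------------------------------------
# scheme objects (bundle parameters for metric evaluation / reports)
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class MaskedMinimizerScheme:
    w: int
    k: int
    mask: Mask
    ordering: Ordering = field(compare=False)

    name = "masked_minimizer"

    def sketch(self, seq: Sequence) -> Sketch:
        return masked_minimizer_sketch(seq, self.w, self.k, self.mask, self.ordering)

    def params(self) -> dict:
        return {"scheme": self.name, "w": self.w, "k": self.k, "s": "",
                "mask": self.mask.to_bitstring()}


@dataclass(frozen=True)
class ParameterizedSyncmerScheme:
    k: int
    s: int
    mask: Mask
    ordering: Ordering = field(compare=False)

    name = "parameterized_syncmer"

    @property
    def w(self) -> int:
        # window parameter used by coverage; for syncmers the natural
        # context width is ks, the number of s-mers per k-mer
        return self.mask.width

    def sketch(self, seq: Sequence) -> Sketch:
        return parameterized_syncmer_sketch(seq, self.k, self.s, self.mask, self.ordering)

    def params(self) -> dict:
        return {"scheme": self.name, "w": "", "k": self.k, "s": self.s,
                "mask": self.mask.to_bitstring()}
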