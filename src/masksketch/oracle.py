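"""Literal, loop-based reference implementations of the four schemes.

These oracles re-derive every window / k-mer decision by exhaustive
scanning with per-string score calls and no vectorized reuse.  They are
deliberately slow (intended for L up to ~10^4) and exist so the
efficient kernels in :mod:`masksketch.schemes` can be cross-checked
against an independent evaluation path.
"""

from __future__ import annotations

from .mask import Mask
from .ordering import Ordering
from .schemes import Sketch
from .sequence import Sequence


def _scan_min_offset(seq: Sequence, ordering: Ordering, a: int, b: int) -> int:
    """Leftmost argmin of score over the b candidates starting at a."""
    best_j, best_score = 0, ordering.score(seq.kmer(a, ordering.k))
    for j in range(1, b):
        sc = ordering.score(seq.kmer(a + j, ordering.k))
        if sc < best_score:
            best_j, best_score = j, sc
    return best_j


def naive_masked_minimizer(
    seq: Sequence, w: int, k: int, mask: Mask, ordering: Ordering
) -> Sketch:
    lwk = seq.n_windows(w, k)
    qualifying = set(mask)
    picks = set()
    for i in range(lwk):
        m = _scan_min_offset(seq, ordering, i, w)
        if m in qualifying:
            picks.add(i + m)
    return Sketch(sorted(picks), k)


def naive_minimizer(seq: Sequence, w: int, k: int, ordering: Ordering) -> Sketch:
    return naive_masked_minimizer(seq, w, k, Mask.full(w), ordering)


def naive_parameterized_syncmer(
    seq: Sequence, k: int, s: int, mask: Mask, ordering: Ordering
) -> Sketch:
    if not 1 <= s < k:
        raise ValueError(f"need 1 <= s < k, got s={s}, k={k}")
    ks = k - s + 1
    if mask.width != ks:
        raise ValueError(f"mask width {mask.width} != ks = {ks}")
    lk = seq.n_kmers(k)
    qualifying = set(mask)
    picks = [i for i in range(lk)
             if _scan_min_offset(seq, ordering, i, ks) in qualifying]
    return Sketch(picks, k)


def naive_open_syncmer(seq: Sequence, k: int, s: int, t: int, ordering: Ordering) -> Sketch:
    return naive_parameterized_syncmer(seq, k, s, Mask.single(k - s + 1, t), ordering)
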