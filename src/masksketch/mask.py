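"""Qualifying-offset masks.

A mask is a subset v of [0, width-1].  For masked minimizers the width is
the window size w; for parameterized syncmers it is ks = k - s + 1, the
number of s-mers per k-mer.  The empty mask is a valid (vacuous) scheme;
the full mask recovers plain minimizers / all-offset syncmers.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np


class Mask:
    """An immutable subset of offsets within ``[0, width - 1]``."""

    __slots__ = ("width", "_offsets")

    def __init__(self, width: int, offsets: Iterable[int]):
        if width < 1:
            raise ValueError(f"mask width must be >= 1, got {width}")
        offs = sorted(set(int(o) for o in offsets))
        if offs and (offs[0] < 0 or offs[-1] >= width):
            raise ValueError(f"offsets {offs} outside [0, {width - 1}]")
        self.width = int(width)
        self._offsets = tuple(offs)

    # -- canonical constructors ----------------------------------------

    @classmethod
    def full(cls, width: int) -> "Mask":
        """The minimizer mask v = [0, w-1]."""
        return cls(width, range(width))

    @classmethod
    def empty(cls, width: int) -> "Mask":
        return cls(width, ())

    @classmethod
    def single(cls, width: int, t: int) -> "Mask":
        """The open-syncmer mask v = {t}."""
        return cls(width, (t,))

    @classmethod
    def closed(cls, width: int) -> "Mask":
        """The closed-syncmer mask v = {0, width-1}."""
        return cls(width, (0, width - 1))

    @classmethod
    def complement(cls, width: int, t: int) -> "Mask":
        """All offsets except t: combines minimizer-like coverage with
        syncmer-like tolerance of low-complexity runs."""
        return cls(width, (o for o in range(width) if o != t))

    # -- set interface --------------------------------------------------

    @property
    def offsets(self) -> tuple[int, ...]:
        return self._offsets

    def __len__(self) -> int:
        return len(self._offsets)

    def __iter__(self) -> Iterator[int]:
        return iter(self._offsets)

    def __contains__(self, offset: int) -> bool:
        return offset in set(self._offsets)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Mask)
            and self.width == other.width
            and self._offsets == other._offsets
        )

    def __hash__(self) -> int:
        return hash((self.width, self._offsets))

    def __le__(self, other: "Mask") -> bool:
        """Subset test (requires equal widths)."""
        if self.width != other.width:
            raise ValueError("cannot compare masks of different widths")
        return set(self._offsets) <= set(other._offsets)

    def is_full(self) -> bool:
        return len(self._offsets) == self.width

    def prune(self, offset: int) -> "Mask":
        """A copy with ``offset`` removed."""
        if offset not in self:
            raise ValueError(f"offset {offset} not in mask")
        return Mask(self.width, (o for o in self._offsets if o != offset))

    def indicator(self) -> np.ndarray:
        """Boolean indicator vector of length ``width``."""
        ind = np.zeros(self.width, dtype=bool)
        ind[list(self._offsets)] = True
        return ind

    # -- serialization --------------------------------------------------

    def to_bitstring(self) -> str:
        """E.g. Mask(7, [0..4, 6]) -> '1111101' (index 0 leftmost)."""
        return "".join("1" if o in set(self._offsets) else "0" for o in range(self.width))

    @classmethod
    def parse(cls, text: str, width: int | None = None) -> "Mask":
        """Parse either a bit-string ('1111101') or comma-separated
        offsets ('0,1,2,3,4,6', width required).  'full' / 'empty' are
        accepted with an explicit width."""
        text = text.strip()
        if text in ("full", "empty"):
            if width is None:
                raise ValueError(f"mask {text!r} needs an explicit width")
            return cls.full(width) if text == "full" else cls.empty(width)
        if text and set(text) <= {"0", "1"} and (width is None or len(text) == width):
            return cls(len(text), (i for i, b in enumerate(text) if b == "1"))
        if width is None:
            raise ValueError("offset-list masks need an explicit width")
        offsets = [int(tok) for tok in text.split(",") if tok != ""]
        return cls(width, offsets)

    def __repr__(self) -> str:
        return f"Mask(width={self.width}, offsets={list(self._offsets)})"
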