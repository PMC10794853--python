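"""Synthetic sequence generation and the substitution homolog model p_S.

Two sequence generators are provided: i.i.d. uniform sequences, and
homopolymer-rich sequences in which non-overlapping single-base runs of
length >= ``homopolymer_min_run`` cover a chosen fraction of positions.
Homopolymer runs are the classic repeated-sampling pitfall for
minimizer schemes whose mask contains offset 0 (leftmost tie-breaking
selects every window's first k-mer inside a run).

Homologs are substitution-only: each base independently mutates with
probability ``substitution_rate`` to one of the three other bases, never
silently, so the rate equals the expected Hamming fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .sequence import DNA, Sequence


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic-sequence study conditions."""

    L: int = 100_000
    alphabet: str = DNA
    homopolymer_fraction: float = 0.002
    homopolymer_min_run: int = 20
    substitution_rate: float = 0.05
    n_homologs: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.L < 1:
            raise ValueError(f"L must be >= 1, got {self.L}")
        for name in ("homopolymer_fraction", "substitution_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.homopolymer_min_run < 1:
            raise ValueError("homopolymer_min_run must be >= 1")

    def as_dict(self) -> dict:
        return asdict(self)


def random_sequence(L: int, alphabet: str = DNA, seed: int = 0) -> Sequence:
    """i.i.d. uniform sequence of length L; reproducible under seed."""
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, len(alphabet), size=L)
    return Sequence("".join(alphabet[c] for c in codes), alphabet=alphabet)


def homopolymer_sequence(config: SimConfig) -> Sequence:
    """Uniform random sequence with planted single-base runs.

    Non-overlapping runs of exactly ``homopolymer_min_run`` bases are
    placed at seeded random positions until the covered fraction reaches
    ``homopolymer_fraction * L`` (to within one run length).  With
    fraction 0 this is exactly :func:`random_sequence`; with fraction 1
    the whole sequence is one run.
    """
    L, frac, run = config.L, config.homopolymer_fraction, config.homopolymer_min_run
    target = frac * L
    if frac > 0 and target < run and frac < 1.0:
        raise ValueError(
            f"homopolymer_fraction {frac} * L {L} < min run length {run}: infeasible"
        )
    rng = np.random.default_rng(config.seed)
    base = random_sequence(L, config.alphabet, seed=config.seed)
    if frac == 0.0:
        return base
    if frac == 1.0:
        sym = config.alphabet[rng.integers(len(config.alphabet))]
        return Sequence(sym * L, alphabet=config.alphabet)

    codes = base.codes.copy()
    occupied = np.zeros(L, dtype=bool)
    covered = 0
    attempts = 0
    while covered < target:  # may overshoot by < one run length
        start = int(rng.integers(0, L - run + 1))
        attempts += 1
        if attempts > 1000 * max(1, int(target / run)):
            raise ValueError("could not place homopolymer runs (fraction too high?)")
        if occupied[max(0, start - 1) : min(L, start + run + 1)].any():
            continue  # keep runs non-overlapping and non-adjacent
        sym = int(rng.integers(len(config.alphabet)))
        codes[start : start + run] = sym
        occupied[start : start + run] = True
        covered += run
    s = "".join(config.alphabet[c] for c in codes)
    return Sequence(s, alphabet=config.alphabet)


def mutate(seq: Sequence, rate: float, seed: int = 0) -> Sequence:
    """Substitution-only homolog draw from p_S.

    Each position independently flips with probability ``rate`` to a
    uniformly chosen *different* symbol (substitutions are never silent).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    n_sym = len(seq.alphabet)
    codes = seq.codes.copy().astype(np.int64)
    hit = rng.random(seq.L) < rate
    # uniform over the n-1 other symbols: add 1..n-1 mod n
    shift = rng.integers(1, n_sym, size=seq.L)
    codes[hit] = (codes[hit] + shift[hit]) % n_sym
    return Sequence("".join(seq.alphabet[c] for c in codes), alphabet=seq.alphabet)


def homolog_panel(
    seq: Sequence, n: int, rate: float, seed: int = 0
) -> list[Sequence]:
    """n independent homolog draws with per-draw seeds derived from seed."""
    root = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(n)]
    return [mutate(seq, rate, seed=cs) for cs in child_seeds]
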