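"""Sketch quality metrics: density, conservation, w-coverage and GSS.

* density  D = |sketch| / Lk                        (lower is better)
* conservation  C = E_{S'~p_S} |sketch(S) ∩ sketch(S')| / Lk, estimated
  by Monte Carlo over substitution-mutated homologs (higher is better);
  C <= D always, since the intersection is a subset of the sketch
* w-coverage  V_w = fraction of (w,k)-windows overlapping >= 1 sampled
  k-mer (a full-mask minimizer sketch has V_w = 1 by construction)
* GSS  G_w = (C / D) * V_w, in [0, 1]; defined as 0 for an empty sketch
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .schemes import Sketch
from .sequence import Sequence

#: slack for float/Monte-Carlo comparisons of the C <= D bound
EPS = 1e-12


def density(sketch: Sketch, lk: int) -> float:
    """|sketch| / Lk."""
    if lk < 1:
        raise ValueError(f"Lk must be >= 1, got {lk}")
    return len(sketch) / lk


def conservation(sketch_ref: Sketch, homolog_sketches: list[Sketch], lk: int) -> float:
    """Mean over homologs of |sketch(S) ∩ sketch(S')| / Lk.

    Sketches are index sets; positions align because homologs are
    substitution-only copies of equal length.
    """
    if not homolog_sketches:
        raise ValueError("need at least one homolog sketch")
    shared = [sketch_ref.intersection_size(sk) for sk in homolog_sketches]
    return float(np.mean(shared)) / lk


def w_coverage(sketch: Sketch, seq: Sequence, w: int, k: int) -> float:
    """Fraction of (w,k)-windows overlapping >= 1 sketched k-mer.

    Window i (0-based) overlaps index j iff i <= j <= i + w - 1.
    """
    lwk = seq.n_windows(w, k)
    if len(sketch) == 0:
        return 0.0
    # difference-array interval cover: pick j covers windows
    # [max(0, j - w + 1), min(lwk - 1, j)]
    delta = np.zeros(lwk + 1, dtype=np.int64)
    j = sketch.indices
    lo = np.clip(j - w + 1, 0, None)
    hi = np.clip(j, None, lwk - 1)
    ok = lo <= hi
    np.add.at(delta, lo[ok], 1)
    np.add.at(delta, hi[ok] + 1, -1)
    covered = np.cumsum(delta[:-1]) > 0
    return float(covered.mean())


def gss(density_: float, conservation_: float, coverage: float) -> float:
    """(C / D) * V_w; 0 by definition when D = 0 (empty sketch)."""
    if density_ == 0.0:
        return 0.0
    return (conservation_ / density_) * coverage


@dataclass(frozen=True)
class MetricReport:
    """All four metrics for one (scheme, sequence, homolog-draw) triple."""

    density: float
    conservation: float
    coverage: float
    gss: float
    n_homologs: int
    substitution_rate: float
    seed: int

    def __post_init__(self):
        if self.conservation > self.density + EPS:
            raise ValueError(
                f"conservation {self.conservation} exceeds density {self.density}"
            )
        if not -EPS <= self.gss <= 1 + EPS:
            raise ValueError(f"GSS {self.gss} outside [0, 1]")

    def as_dict(self) -> dict:
        return asdict(self)


def evaluate_scheme(
    scheme,
    seq: Sequence,
    homologs: list[Sequence] | None = None,
    n_homologs: int = 8,
    substitution_rate: float = 0.05,
    seed: int = 0,
) -> MetricReport:
    """Sketch ``seq`` and its homologs with ``scheme`` and report metrics.

    If ``homologs`` is None they are drawn by i.i.d. base substitution at
    ``substitution_rate`` from ``seed``.  Passing explicit homologs lets
    callers reuse identical draws across schemes (common random numbers),
    which is what makes mask-monotonicity of conservation hold pointwise.
    """
    from .simulate import mutate

    if homologs is None:
        homologs = [
            mutate(seq, substitution_rate, seed=(seed + 7919 * i) % 2**31)
            for i in range(n_homologs)
        ]
    for h in homologs:
        if h.L != seq.L:
            raise ValueError("homolog length differs from reference (indels unsupported)")

    sk = scheme.sketch(seq)
    lk = seq.n_kmers(scheme.k)
    d = density(sk, lk)
    hom_sketches = [scheme.sketch(h) for h in homologs]
    c = conservation(sk, hom_sketches, lk)
    cov = w_coverage(sk, seq, scheme.w, scheme.k)
    return MetricReport(
        density=d,
        conservation=c,
        coverage=cov,
        gss=gss(d, c, cov),
        n_homologs=len(homologs),
        substitution_rate=substitution_rate,
        seed=seed,
    )
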