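"""Outer-loop mask search: greedy pruning and exhaustive enumeration.

The greedy search starts from the complete qualifying set v = [0, w-1],
runs one inner-loop ordering optimization per candidate mask, and
repeatedly removes the single offset whose removal most improves GSS,
stopping when no removal improves it (or the mask empties).  The search
is heuristic; with at most w acceptance rounds and at most w trials per
round it costs at most w(w+1)/2 + 1 inner-loop runs.

Sibling trials at one depth share homolog draws and training seeds
(common random numbers), so trial GSS differences reflect masks rather
than sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable

import pandas as pd

from .mask import Mask
from .metrics import MetricReport, evaluate_scheme
from .schemes import MaskedMinimizerScheme, sketch_from_scores
from .sequence import Sequence
from .simulate import homolog_panel
from .train import TrainConfig, train_ordering

#: an evaluator maps a mask to (gss, payload); payload is kept for the best mask
Evaluator = Callable[[Mask], tuple[float, object]]


@dataclass
class PruneState:
    """Search trace: accepted path and every trial evaluated."""

    mask: Mask
    best_gss: float = 0.0
    best_mask: Mask | None = None
    trial_log: list[tuple[Mask, float, int]] = field(default_factory=list)

    @property
    def n_inner_calls(self) -> int:
        return len(self.trial_log)

    def log(self, mask: Mask, gss_value: float, depth: int) -> None:
        self.trial_log.append((mask, gss_value, depth))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"mask": m.to_bitstring(), "n_bits": len(m), "gss": g, "depth": d}
                for m, g, d in self.trial_log
            ]
        )


def default_evaluator(
    seq: Sequence,
    w: int,
    k: int,
    config: TrainConfig,
    loss: str = "gss",
) -> Evaluator:
    """Train-and-evaluate with a fixed held-out homolog panel (CRN)."""
    panel = homolog_panel(
        seq, config.n_eval_homologs, config.substitution_rate,
        seed=(config.seed + 104729) % 2**31,
    )

    def evaluate(mask: Mask) -> tuple[float, object]:
        if len(mask) == 0:
            return 0.0, None
        pmodel, tmodel, history = train_ordering(
            seq, w, k, mask, config, loss=loss, eval_homologs=panel
        )
        return history[-1].gss, (pmodel, tmodel, history)

    return evaluate


def greedy_prune(
    seq: Sequence | None,
    w: int,
    k: int,
    config: TrainConfig = TrainConfig(),
    loss: str = "gss",
    evaluator: Evaluator | None = None,
) -> tuple[Mask, object, PruneState]:
    """Bi-level masked-minimizer optimization (greedy mask descent).

    Returns the best mask, the payload its evaluation produced (for the
    default evaluator: the trained models and metric trajectory), and
    the full :class:`PruneState` trace.  A custom ``evaluator`` replaces
    the inner loop, e.g. for testing the search logic in isolation.
    """
    if w < 1:
        raise ValueError(f"w must be >= 1, got {w}")
    if evaluator is None:
        if seq is None:
            raise ValueError("need a sequence unless an evaluator is supplied")
        evaluator = default_evaluator(seq, w, k, config, loss)

    state = PruneState(mask=Mask.full(w), best_mask=Mask.full(w))
    best_gss = 0.0
    mask = Mask.full(w)
    gss_value, best_payload = evaluator(mask)
    state.log(mask, gss_value, 0)
    depth = 0
    while gss_value > best_gss and len(mask) > 0:
        best_gss = gss_value
        best_mask = mask
        state.best_gss, state.best_mask = best_gss, best_mask
        if len(mask) == 1:
            break  # only the empty mask remains; it cannot improve GSS
        depth += 1
        for offset in mask:  # ascending: smallest offset wins ties
            trial = mask.prune(offset)
            trial_gss, payload = evaluator(trial)
            state.log(trial, trial_gss, depth)
            if trial_gss > gss_value:
                gss_value = trial_gss
                best_mask = trial
                best_payload = payload
        mask = best_mask
    state.mask = mask
    return state.best_mask, best_payload, state


def all_masks(w: int, include_empty: bool = False):
    """All masks over [0, w-1] in order of increasing cardinality."""
    lo = 0 if include_empty else 1
    for size in range(lo, w + 1):
        for offs in combinations(range(w), size):
            yield Mask(w, offs)


def exhaustive_mask_sweep(
    seq: Sequence,
    w: int,
    k: int,
    config: TrainConfig = TrainConfig(),
    loss: str = "gss",
    train_per_mask: bool = True,
    max_w: int = 12,
) -> pd.DataFrame:
    """Evaluate every non-empty mask over [0, w-1] (2^w - 1 schemes).

    With ``train_per_mask=True`` each mask gets its own inner loop (the
    orderings differ, so density/conservation need not be monotone
    across mask inclusion).  With ``train_per_mask=False`` a single
    ordering is trained once on the full mask and shared, and all masks
    are scored against the same homolog draws; along any chain
    v ⊆ v' the sketch, density and conservation columns are then
    monotone exactly.
    """
    if w > max_w:
        raise ValueError(f"w = {w} too large for exhaustive sweep (max {max_w})")
    panel = homolog_panel(
        seq, config.n_eval_homologs, config.substitution_rate,
        seed=(config.seed + 104729) % 2**31,
    )
    rows = []
    shared_scores = None
    if not train_per_mask:
        pmodel, _, _ = train_ordering(
            seq, w, k, Mask.full(w), config, loss=loss, eval_homologs=panel
        )
        shared_scores = pmodel.score_vector(seq)
        shared_hom_scores = [pmodel.score_vector(h) for h in panel]

    from .metrics import conservation, density, gss, w_coverage

    lk = seq.n_kmers(k)
    for mask in all_masks(w):
        if train_per_mask:
            pmodel, _, history = train_ordering(
                seq, w, k, mask, config, loss=loss, eval_homologs=panel
            )
            rep = history[-1]
        else:
            sk = sketch_from_scores(shared_scores, w, mask, k)
            hom_sk = [sketch_from_scores(s, w, mask, k) for s in shared_hom_scores]
            d = density(sk, lk)
            c = conservation(sk, hom_sk, lk)
            cov = w_coverage(sk, seq, w, k)
            rep = MetricReport(d, c, cov, gss(d, c, cov), len(panel),
                               config.substitution_rate, config.seed)
        rows.append({"mask": mask.to_bitstring(), "n_bits": len(mask),
                     **rep.as_dict()})
    return pd.DataFrame(rows)
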