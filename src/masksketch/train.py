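"""Inner-loop ordering optimization for a fixed mask.

``train_ordering`` runs seeded stochastic gradient descent (Adam) on the
priority and template models over randomly sampled subsequences of the
target.  Every ``eval_interval`` epochs the masked-minimizer sketch
induced by the current priority scores is evaluated on the full sequence
against a fixed held-out homolog panel (common random numbers), so the
metric trajectories of different losses and masks are directly
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .losses import conservation_loss_grads, density_loss_grads, gss_loss_grads
from .mask import Mask
from .metrics import MetricReport, conservation, density, gss, w_coverage
from .models import Adam, PriorityModel, TemplateModel
from .ordering import Ordering
from .schemes import Sketch, sketch_from_scores
from .sequence import Sequence
from .simulate import homolog_panel

LOSSES = ("dm", "con", "gss")


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the inner loop (all defaults logged in output).

    ``lambda_reg`` is the regularization trade-off in the density loss;
    ``lambda_con`` balances density against conservation in the GSS loss;
    ``n_homologs`` is the number of fresh homolog draws per epoch for the
    conservation term; ``batch_span`` is the subsequence length (bases)
    sampled per gradient step.
    """

    lambda_reg: float = 1.0
    lambda_con: float = 1.0
    n_homologs: int = 2
    epochs: int = 300
    batch_span: int = 6000
    learning_rate: float = 3e-3
    seed: int = 0
    tau: float = 0.1
    weight_mode: str = "softmin"
    hidden: int = 64
    order: int = 3
    substitution_rate: float = 0.05
    n_eval_homologs: int = 8
    eval_interval: int = 10

    def __post_init__(self):
        for name in ("lambda_reg", "lambda_con", "learning_rate", "tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.epochs < 0 or self.batch_span < 1:
            raise ValueError("epochs must be >= 0 and batch_span >= 1")

    def as_dict(self) -> dict:
        return asdict(self)


class PriorityOrdering(Ordering):
    """A trained priority model wrapped as a k-mer ordering."""

    def __init__(self, model: PriorityModel):
        super().__init__(model.k)
        self.model = model

    def score_codes(self, codes: np.ndarray) -> np.ndarray:
        return self.model.score_codes(codes)


def scores_to_ordering(model: PriorityModel) -> PriorityOrdering:
    """Wrap a priority model as an Ordering, checking determinism.

    Inference must be deterministic and content-based; this is verified
    by scoring a duplicated k-mer batch and requiring identical outputs.
    """
    probe = np.tile(np.arange(model.k, dtype=np.int64) % model.alphabet_size, (2, 1))
    s = model.score_codes(probe)
    if s[0] != s[1]:
        raise ValueError("priority model scores are not deterministic")
    return PriorityOrdering(model)


def _mutate_codes(codes: np.ndarray, rate: float, rng: np.random.Generator,
                  n_symbols: int = 4) -> np.ndarray:
    out = codes.astype(np.int64).copy()
    hit = rng.random(len(out)) < rate
    shift = rng.integers(1, n_symbols, size=len(out))
    out[hit] = (out[hit] + shift[hit]) % n_symbols
    return out


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(codes, k)


def evaluate_model(
    pmodel: PriorityModel,
    seq: Sequence,
    w: int,
    mask: Mask,
    eval_homologs: list[Sequence],
    substitution_rate: float,
    seed: int,
) -> MetricReport:
    """Metrics of the masked-minimizer sketch induced by current scores."""
    k = pmodel.k
    lk = seq.n_kmers(k)
    sk = sketch_from_scores(pmodel.score_vector(seq), w, mask, k)
    hom_sketches = [
        sketch_from_scores(pmodel.score_vector(h), w, mask, k) for h in eval_homologs
    ]
    d = density(sk, lk)
    c = conservation(sk, hom_sketches, lk)
    cov = w_coverage(sk, seq, w, k)
    return MetricReport(d, c, cov, gss(d, c, cov), len(eval_homologs),
                        substitution_rate, seed)


def train_ordering(
    seq: Sequence,
    w: int,
    k: int,
    mask: Mask,
    config: TrainConfig = TrainConfig(),
    loss: str = "gss",
    eval_homologs: list[Sequence] | None = None,
) -> tuple[PriorityModel, TemplateModel, list[MetricReport]]:
    """Optimize the ordering for a fixed mask; returns models + trajectory.

    ``loss`` is one of ``"dm"`` (density only), ``"con"`` (conservation
    term only) or ``"gss"`` (both).  ``eval_homologs`` may be passed
    explicitly so several runs share identical held-out draws.
    """
    if loss not in LOSSES:
        raise ValueError(f"loss must be one of {LOSSES}, got {loss!r}")
    if mask.width != w:
        raise ValueError(f"mask width {mask.width} != w = {w}")
    wk = w + k - 1
    span = min(config.batch_span, seq.L)
    if span < wk:
        raise ValueError(f"batch_span {span} shorter than window length {wk}")
    seq.n_windows(w, k)

    root = np.random.SeedSequence(config.seed)
    s_init_p, s_init_t, s_batch, s_eval = (
        int(s.generate_state(1)[0] % 2**31) for s in root.spawn(4)
    )
    pmodel = PriorityModel(k, hidden=config.hidden, order=min(config.order, k),
                           seed=s_init_p)
    tmodel = TemplateModel(w, seed=s_init_t)
    opt_p = Adam(pmodel.params, lr=config.learning_rate)
    opt_t = Adam(tmodel.params, lr=config.learning_rate)
    rng = np.random.default_rng(s_batch)

    if eval_homologs is None:
        eval_homologs = homolog_panel(
            seq, config.n_eval_homologs, config.substitution_rate, seed=s_eval
        )

    def _eval() -> MetricReport:
        return evaluate_model(pmodel, seq, w, mask, eval_homologs,
                              config.substitution_rate, config.seed)

    history = [_eval()]
    n_kmers_batch = span - k + 1
    for epoch in range(1, config.epochs + 1):
        start = int(rng.integers(0, seq.L - span + 1))
        codes = seq.codes[start : start + span]
        kmers = _kmer_codes(codes, k)
        positions = np.arange(start, start + n_kmers_batch)

        x_ref = pmodel.encode(kmers)
        p_ref, cache_ref = pmodel.forward(x_ref)
        t_vec, cache_t = tmodel.forward(positions)

        hom_caches: list = []
        p_homs: list[np.ndarray] = []
        if loss in ("con", "gss"):
            for _ in range(config.n_homologs):
                hcodes = _mutate_codes(codes, config.substitution_rate, rng)
                xh = pmodel.encode(_kmer_codes(hcodes, k))
                ph, ch = pmodel.forward(xh)
                p_homs.append(ph)
                hom_caches.append(ch)

        if loss == "dm":
            _, gp, gt = density_loss_grads(
                p_ref, t_vec, mask, config.lambda_reg, config.tau, config.weight_mode
            )
            g_homs = []
        elif loss == "gss":
            _, gp, g_homs, gt = gss_loss_grads(
                p_ref, p_homs, t_vec, mask, config.lambda_reg, config.lambda_con,
                config.tau, config.weight_mode,
            )
        else:  # con
            _, g_homs, gt = conservation_loss_grads(
                p_homs, t_vec, mask, config.lambda_reg, config.tau, config.weight_mode
            )
            gp = None

        grads_p = None
        if gp is not None:
            grads_p = pmodel.backward(cache_ref, gp)
        for ch, gph in zip(hom_caches, g_homs):
            gh = pmodel.backward(ch, gph)
            if grads_p is None:
                grads_p = gh
            else:
                for key in grads_p:
                    grads_p[key] += gh[key]
        grads_t = tmodel.backward(cache_t, gt)
        opt_p.step(grads_p)
        opt_t.step(grads_t)

        if epoch % config.eval_interval == 0 or epoch == config.epochs:
            history.append(_eval())

    return pmodel, tmodel, history
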