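# Methods

## Sampling schemes

All schemes operate on uppercase sequences over Σ = {A, C, G, T}
(symbols outside Σ are rejected at input, or the sequence is split at
such runs when requested).  Coordinates are 0-based throughout; a
sequence of length L has L_k = L − k + 1 k-mers and
L_wk = L − (w + k − 1) + 1 windows of w consecutive k-mers.

An ordering is a deterministic scoring function f : Σ^k → [0, 1];
k-mers with equal scores are ranked by order of appearance in the
window (leftmost wins).  The index selector m_f(a, b) returns the
offset of the lowest-scoring k-mer among the b candidates starting at
a.  The four schemes:

* **minimizer** — {i + m_f(i, w)} over all windows i;
* **masked minimizer** — the same picks, kept only when
  m_f(i, w) ∈ v for the mask v ⊆ [0, w−1];
* **open syncmer** — all k-mers i whose minimal constituent s-mer
  (s < k, k_s = k − s + 1 of them) sits exactly at offset t;
* **parameterized syncmer** — offset anywhere in v ⊆ [0, k_s−1].

The masked-minimizer picks are monotone in the mask (v ⊆ v′ implies
sketch(v) ⊆ sketch(v′)): a pick qualifies through some window whose
selector offset is in v, hence also in v′.  Density and conservation
inherit this monotonicity; the test suite asserts all three on hundreds
of randomized instances, and every efficient kernel is cross-checked
against a literal per-window scanning oracle (`masksketch.oracle`).

The open-syncmer offset is validated against t ∈ [0, k_s − 1], the
range induced by the k_s constituent s-mers.

## Metrics

For a sketch X of S with homolog distribution p_S:

* density D = |X| / L_k;
* conservation C = E_{S′∼p_S} |X(S) ∩ X(S′)| / L_k, estimated by Monte
  Carlo (default 8 substitution-mutated homologs at rate 0.05, all
  draws seeded).  The intersection is over k-mer start indices —
  homologs have equal length, so positions align; indels are out of
  scope.
* w-coverage V_w = fraction of windows overlapping ≥ 1 pick, where
  window i holds k-mer indices [i, i + w − 1];
* GSS G_w = (C / D) · V_w, defined as 0 when the sketch is empty
  (D = 0 forces V_w = 0 as well).

C ≤ D holds pointwise per homolog draw, so comparisons between masks
reuse identical homolog draws (common random numbers); that is what
makes the conservation-monotonicity inequality hold exactly rather
than in expectation.  `MetricReport` re-validates C ≤ D + 1e−12 and
G_w ∈ [0, 1] at construction, so every evaluation anywhere in the
package enforces the bounds.

## Synthetic data

`random_sequence` draws i.i.d. uniform bases.  `homopolymer_sequence`
plants non-overlapping single-base runs (fixed length
`homopolymer_min_run`, default 20) at random positions until a target
fraction of positions is covered (to within one run length).
"Homopolymer content" is operationalized as the fraction of positions
inside planted runs.  `mutate` flips each base independently with the
given rate to a uniformly chosen *different* base, so the rate equals
the expected Hamming fraction.  Everything is reproducible from a
single seed; homolog panels derive per-draw seeds from a seed sequence.

What the generators emulate — and what they do not: uniform sequences
have essentially unique k-mers at the sizes used here (k ≈ 15), no
repeat structure, and no compositional bias.  Real genomes contain
repeats, low-complexity tracts and skewed base composition; passing
the randomized tests therefore demonstrates correctness of the
algorithms and the direction of the optimization effects, not the
magnitudes one would measure on a genome.

## The optimizer

The inner loop learns an ordering for a fixed mask with two small
models, trained jointly by Adam (default lr 3e−3) on randomly sampled
subsequences (default span 6000 bases) for a fixed number of epochs:

* **priority model** — scores each k-mer from its content only: the
  identities of its positional trinucleotides feed an embedding sum
  (equivalent to a dense layer over one-hot n-grams), a tanh hidden
  layer (default 64 units) and a logistic output.  Content-determinism
  makes the score vector a valid ordering wherever a k-mer occurs.
  The n-gram order is configurable; order 3 is the default because a
  single substitution perturbs up to three feature blocks, giving the
  model enough sharpness for robustness differences between orderings
  to be expressible.  Inference avoids BLAS matvecs whose rounding
  depends on row alignment, so identical k-mers score bit-identically.
* **template model** — scores positions only:
  T[m] = σ(a·cos(2π(m − φ)/w) + b + c[m mod w]) with trainable
  amplitude, phase, bias and per-residue correction.  Its minima recur
  once per period, so the sketch induced by T alone has density ≈ 1/w
  from initialization (asserted within a factor of 2 in the tests).

**Density loss.**  L_DM(P, T; v) = λ‖1 − P‖² + Σ_i Σ_{j∈v}
ω_ij (P[i+j] − T[i+j])², one inner sum per window over the qualifying
offsets.  The default weighting ω_i· is a softmin of the window's
qualifying template values (temperature τ = 0.1), concentrating the
pull of P toward T on the position most likely to be sampled while the
regularizer (λ = 1) pushes all other scores toward 1.  A plain
template-value weighting (ω_ij = T[i+j]) is available as
`weight_mode="template"`; it is simpler but pulls hardest exactly where
the template is high, which blunts the density signal, so softmin is
the default.  Gradients with respect to P and T are closed-form and
verified against finite differences to 1e−4 relative.

**GSS loss.**  L_gss = L_DM(P(S), T) + λ_c · (1/n) Σ_i L_DM(P(S′_i), T)
with λ_c = 1 and n fresh homolog draws per epoch (resampling gives an
unbiased estimate of the expectation over p_S; the same λ applies
inside the homolog terms).  Driving the homolog score vectors toward
the same template concentrates them around P(S), so picks tend to
survive substitution.  On a 10 kb uniform sequence (w = 7, k = 15) this
raises conservation at matched density and yields a higher final GSS
than the density-only loss in 10/10 paired seeds at the sizes used in
the acceptance tests.

Metric trajectories during training are evaluated on the full sequence
against a fixed held-out homolog panel, so runs with different losses
or masks are directly comparable.

**Outer loop.**  Starting from the full mask, one inner loop scores the
current mask; each round then retrains once per set offset with that
offset pruned and accepts the best strictly-improving pruned mask
(ties prune the smallest offset), stopping when no trial improves GSS
or the mask empties.  At most w acceptance rounds of at most w trials
give ≤ w(w+1)/2 + 1 inner-loop runs.  Sibling trials share homolog
draws and training seeds so GSS differences reflect masks, not noise.
`exhaustive_mask_sweep` evaluates all 2^w − 1 non-empty masks for
small w; with `train_per_mask=False` a single trained ordering is
shared by all masks, which is the mode in which the mask-monotonicity
inequalities apply exactly (per-mask retraining changes the ordering,
and the inequalities do not relate sketches under different orderings).

## Numerical and design choices

* Ties in windows are broken strictly by leftmost position
  (`np.argmin` semantics); this is what makes homopolymer runs sample
  repeatedly under masks containing offset 0.
* Sketches are sets: a k-mer picked by several windows is reported
  once.  BED output is 0-based half-open.
* The random one-to-one orderings used in tests hash k-mer codes
  through a 64-bit mixer; collisions are ~2^−64 and irrelevant at test
  sizes.
* Training subsequence spans, epochs and model sizes in the tests are
  deliberately small (10–20 kb sequences, 150 epochs); they are the
  package's desk-scale defaults, chosen so the optimization direction
  is measurable and stable across seeds.
* Degenerate inputs: empty masks produce valid empty sketches with
  zero coverage and GSS; w = 1 minimizers select every k-mer; training
  with zero epochs returns the initialized models plus a baseline
  metric report.

## Known limitations

* Forward strand only; no canonical (strand-symmetric) k-mers.
* Conservation requires equal-length homologs (substitutions only); no
  indel or structural-variant model.
* The homopolymer stress comparison at 0.2% homopolymer content does
  not rank the complement mask v = [1, w−1] above the full mask at
  this scale: the repeated-sampling penalty the runs inflict on the
  full mask (bounded by content/density, ~1–2% of GSS here) is smaller
  than the intrinsic conservation cost of masking (a position may
  qualify via offset 0 in the reference but not in a homolog, or vice
  versa, ~2–3%).  The complement mask does rank clearly above the
  open-syncmer mask v = {0}, and its advantage over the full mask
  grows with homopolymer load; at this content level the full mask
  remains the better scheme in these experiments.
* The greedy mask search is a heuristic; it guarantees monotone
  accepted GSS, not a global optimum.
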