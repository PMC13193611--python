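# Methods

`budscan` detects yeast cell-division (budding) events in lifelong
single-cell phase-contrast movies and derives replicative lifespan (RLS) and
cell-cycle dynamics from them. This note records the model, the synthetic
data it is validated on, the numerical choices, and their limitations.

## The two-stage model

**Stage 1 — masked auto-encoder (MAE).** Each 64 × 64 crop of a tracked
mother cell is split into non-overlapping 8 × 8-px patches (an 8 × 8 token
grid). A random 75% of patches is hidden; the visible tokens, plus a class
token and learnable positional embeddings indexed by *original* patch
position, pass through a small vision-transformer encoder (dim 128, depth 4,
4 heads, pre-norm blocks, GELU MLPs). A lighter decoder (dim 64, depth 2)
receives the encoded visible tokens with a learnable mask token inserted at
every hidden position, unshuffles the sequence back to grid order via the
stored permutation, and predicts pixel values per patch. The loss is the
mean squared error on masked patches only (`loss_on="all"` switches to
all-patch MSE; the masked-only convention is the canonical one and the
default). The reconstruction target is the z-scored pixel value without
per-patch re-normalization.

Training uses AdamW (decoupled weight decay 0.01, applied to matrix-shaped
parameters only), a linear warmup followed by cosine annealing with periodic
restarts (`lr_at` gives the exact closed form), gradient accumulation
(`grad_accum_steps` micro-batches per optimizer update, loss scaled per
micro-batch so the accumulated gradient equals the large-batch gradient),
and an exponential-moving-average (EMA) weight copy (decay 0.999) logged per
epoch. The checkpoint with the best validation loss is retained; validation
masking plans are fixed across epochs so the curve is comparable. The raw
(non-EMA) best checkpoint feeds stage 2; the EMA copy is returned alongside
for inspection.

**Stage 2 — temporal detector.** For division detection the decoder is
dropped and no patches are masked: the encoder embeds every frame as a
single vector. When the encoder is fine-tuned for the task, the class
token's output is that vector (it acquires a summarization role through the
classification gradient). When the encoder stays *frozen*, the class token
of a canonically pretrained MAE has had no summarization objective and is a
poor frame descriptor — frozen-path runs therefore mean-pool the patch-token
outputs instead, the standard protocol for probing frozen
masked-auto-encoder features (`DetectorConfig.frame_embedding` selects; the
desk-scale configuration uses `meanpool`). In our experiments this single
choice was decisive: with frozen CLS embeddings the detector produced
confident false positives on event-free movies that ensembling could not
remove; with mean-pooled embeddings the same training recipe detects
essentially every event and stays silent on event-free inputs.
An 11-frame window (the frame of interest with five
preceding and five subsequent frames) of embeddings, plus fixed sinusoidal
temporal embeddings (`sin/cos(t / 10000^{2i/d})`), passes through a
2-block temporal transformer (dim 128, 4 heads); the center slot's output
token feeds a linear head with two logits converted by softmax into
(non-budding, budding) probabilities for the center frame. Budding frames
are rare, so mini-batches are balanced: each batch holds equal numbers of
positive and negative stacks, the majority class visited at least once per
epoch and the minority oversampled with replacement. The encoder can be
frozen (embeddings computed once; the default for desk-scale runs, where it
makes stage 2 orders of magnitude cheaper) or fine-tuned end-to-end at 10×
lower learning rate (`encoder_mode="finetune"`). Model selection uses
validation F1 at ±1-frame tolerance, computed through the full
prediction-and-post-processing path; the head learning rate follows a
cosine decay across epochs. Frames immediately adjacent to an annotated
event (`ignore_margin`, default ±1) are excluded from the negative pool:
they are near-duplicates of the positive window, the run-merging
post-processing and the ±1-frame scoring tolerance make them equivalent to
the event frame downstream, and forcing the classifier to separate them
from the event frame encourages trigger-happy behavior elsewhere.

The detector is a small deep ensemble: `n_members` (default 5) temporal
heads share the (frozen or fine-tuned) encoder but train from distinct
initializations and batch streams, and inference averages their softmax
probabilities. In the few-training-cell regime a single head occasionally
emits isolated, confident false positives on event-free windows at
member-specific frames — a variance artifact (two windows sharing 10 of 11
frames can score 0.98 and 0.0) — and under-scores borderline events near
the threshold. Averaging suppresses the member-specific hallucinations
while preserving the shared, data-driven event signal. With fine-tuning,
member 0 trains jointly with the encoder and the remaining members train
frozen on the fine-tuned embeddings.

**Post-processing.** Probabilities ≥ threshold (default 0.5) become
positive calls; each maximal run of consecutive positive frames is merged
into one division event, represented by its first frame (bud-emergence
semantics; a midpoint option exists and is recorded in output metadata
because it shifts signed-error statistics). RLS is the event count.
Cell-cycle gaps between successive events are reported in frames and
minutes (15 min/frame by default) at lifespan-fraction positions
100·k/(RLS−1). No refractory/minimum-gap filter is applied by default; an
optional `min_gap` exists but is off.

## Evaluation

Predicted and true events are paired one-to-one by the Hungarian algorithm
with cost |Δframes|, pairings allowed only within `max_gap = 5` frames
(disallowed pairs carry effectively infinite cost, which maximizes the
number of valid pairs before minimizing total offset). From one assignment
we derive: tolerance-window tp/fp/fn and precision/recall/F1 (a pair is a
true positive when |signed error| ≤ tolerance, default ±1), the
exact/early/late/unmatched breakdown and mean signed error (denominated by
predictions, with unmatched predictions their own class; a ground-truth
denomination is available), and per-cell lifespan agreement — OLS fit of
predicted on true RLS with its R², plus an identity-line R² and the sample
SD of (pred − gt). Degenerate denominators yield `None` with an explicit
flag, never silent NaN. Cycle-length trajectories are averaged in
2%-lifespan bins and smoothed with a Savitzky–Golay filter (window 11,
polyorder 2). The untrained baseline runs a randomly initialized detector
(fixed seed) through the identical inference and post-processing path; it
is a diagnostic control, not a competing method.

## Synthetic movies

The generator emulates a mother-machine trap: an elliptical mother body
(radii 10 × 8 px, intensity 0.75 on background 0.2) fixed in a 64 × 64
field with per-frame Gaussian position jitter (σ 0.3 px, clipped at 3σ),
per-frame multiplicative illumination fluctuations (uniform on
[1/1.05, 1.05] in log scale) and per-pixel Gaussian noise (σ 0.05),
intensities clipped to [0, 1] and written as 16-bit TIFF. At each scheduled
division a circular bud appears tangent to the mother on the channel-facing
side (small angular jitter, 0.25 rad), grows linearly to radius 5 px over
4 frames (one hour), and is then flushed away. Overlapping bud episodes
(gap < 4 frames) raise by default or truncate the earlier episode on
request.

Division schedules draw a per-cell RLS from N(15, 4²) (rounded, floored at
1) — a realistic wild-type yeast lifespan — and inter-division gaps from a
linear ramp of expected length 6 frames (90-min young-cell cycle at 15-min
sampling) up to 6 × 2 frames at the end of life, with gap noise σ 1 frame,
floored at 1. Frame 0 is never an event. Every movie extends 20 frames
(5 h) past the final division: real acquisitions image each trap until and
beyond division cessation, and this post-cessation period matters for
training — it is the main source of fully bud-free 11-frame windows, which
teach the classifier to stay silent on event-free inputs. An early version
of the generator lacked this tail and the resulting detectors produced
confident false positives on event-free movies.

What the generator does *not* emulate: phase-contrast optics (halos,
defocus), neighboring cells and trap walls, elongated-daughter
morphologies, segmentation/tracking errors, or gradual death morphology.
Passing the synthetic validation therefore demonstrates that the
architecture, training recipe and post-processing can recover division
timing and lifespan from image sequences with realistic temporal structure
and nuisance variation — not that the shipped defaults reach any particular
accuracy on real microscopy data, which will require retraining on real
crops.

## Desk-scale validation protocol

The reference experiment (`end_to_end_experiment`, also run by
`scripts/acceptance.py`) generates 60 cells and splits them cell-exclusively
into 40 training and 20 held-out evaluation cells; the training cells split
again 80/20 into fit and validation subsets used by both stages. Dataset
z-score normalization statistics come from training cells only and are
reused verbatim everywhere. The MAE pretrains on 2,000 crops subsampled
from the training-fit cells for 12 epochs (batch 64, base lr 1.5e-3, warmup
40 steps, cosine cycle 200 steps — the validation loss plateaus well before
longer schedules at this scale); the detector trains a 5-member ensemble
for 8 epochs per member with the frozen encoder and mean-pooled frame
embeddings. Held-out cells are scored with tolerance ±1 and max_gap 5; the
same held-out cells are scored with the untrained baseline; 10 additional
event-free movies form the negative control; MAE reconstruction is compared
with the per-image-mean reference on 500 held-out crops under fixed masking
plans. On one CPU the whole protocol takes roughly 15 minutes.

## Numerical and design notes

- All arithmetic is float32 (float64 in scoring and statistics); training
  is exactly reproducible for a given seed on a given platform, and every
  source of randomness (simulation, splits, masking, init, sampling) draws
  from named streams spawned from the single run seed.
- The in-package autograd core implements reverse-mode differentiation for
  exactly the operations these models need (broadcasted arithmetic, batched
  matmul, gather/concat, fused layer-norm/GELU/softmax); its gradients are
  tested against central finite differences.
- Ties in the Hungarian assignment (equal total cost) are resolved by the
  assignment solver deterministically; evaluation invariants are asserted
  on pair count and total cost, which are tie-invariant.
- Boundary frames: the first/last five frames of a movie get
  edge-replicated window slots (flagged per slot), so every frame receives
  a prediction; replication avoids fabricating motion at the boundary.
- The annotation convention marks bud emergence as a single frame
  (`positive_span = 1`); the span is configurable because annotation
  granularity varies between datasets.
- `split_by_cell` uses |train| = round(frac·n), clamped so both splits stay
  non-empty; assignments are cell-exclusive by construction and asserted.
- 16-bit TIFF quantization bounds the round-trip error at half a gray level
  (≈ 7.6e-6 in [0, 1] units), exercised by the reader tests.

## Known limitations

- The nuisance model is additive/multiplicative and unstructured; real
  phase-contrast artifacts are spatially correlated and can mimic bud
  edges. Expect the frozen-encoder desk configuration to need fine-tuning
  (or full retraining of stage 1) on real data.
- Death is modeled only as cessation of budding; no lysis or morphology
  change is rendered, so end-of-life detection beyond the last division is
  out of scope.
- The detector emits one probability per center frame; events closer than
  2 frames cannot be resolved as separate events after run-merging.
- Single-device training only; no mixed precision or distribution.
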