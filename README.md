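# budscan

Automated detection of yeast cell-division (budding) events in lifelong
single-cell time-lapse movies, and quantification of replicative lifespan
(RLS) and cell-cycle dynamics.

## The problem

In microfluidic "mother machine" devices, single *S. cerevisiae* mother
cells are trapped and imaged every 15 minutes for days while their daughters
are flushed away. The number of daughters a mother produces before ceasing
division — its replicative lifespan — and the timing of each division are
the core read-outs of replicative-aging experiments. Scoring them by hand
means annotating every bud emergence across hundreds of frames per cell,
for hundreds of cells.

`budscan` implements a two-stage, annotation-efficient detector:

1. **Self-supervised pretraining.** A masked auto-encoder (MAE) learns
   morphology-aware representations from *unlabeled* 64 × 64 crops: 75% of
   8 × 8-px patches are hidden and a small vision transformer (encoder
   dim 128 / depth 4) is trained to reconstruct them, minimizing the masked
   L2 loss

   L = mean over masked patches of ‖x̂ₚ − xₚ‖²,

   with AdamW, warmup + cosine-restart learning rates, gradient
   accumulation and an EMA weight copy.
2. **Temporal division detection.** With the encoder frozen (or fine-tuned),
   each frame is embedded via a class token; an 11-frame window
   (center ± 5) with sinusoidal temporal embeddings passes through a
   lightweight temporal transformer whose center-slot output yields
   softmax probabilities P(budding at center frame). Balanced mini-batches
   handle the heavy class imbalance.

Post-processing thresholds the per-frame probabilities, merges consecutive
positive frames into single division events, and emits per cell: (i) RLS
(the event count), (ii) event timing, (iii) the frame-wise probability
trace, plus cell-cycle-length series over lifespan fraction.

Evaluation pairs predicted and true events one-to-one with the Hungarian
algorithm (≤ 5-frame offsets), reporting tolerance-window precision /
recall / F1 (±1 frame by default), the exact/early/late/unmatched
breakdown with mean signed error, and per-cell RLS agreement (R², error
SD). A synthetic mother-machine movie generator with exact ground truth
(known division schedules, configurable noise, jitter and illumination
drift, and a post-cessation tail) makes the whole pipeline trainable and
testable at desk scale with no external data.

## Worked example

`examples/` contains one narrative script per capability. The quickest
round trip — simulate 16 cells with known schedules, train both stages,
read out a held-out cell — is `examples/03_detect_divisions.py` (a few
minutes on one CPU):

```sh
$ python examples/03_detect_divisions.py
...
member 2 epoch 9: loss 0.0002 val F1(+/-1) 0.972

held-out cell cell_001:
  true division frames:      [4, 10, 17, 24, 32, 42, 51, 59, 69, 79, 88, 98, 110, 120, 132]
  predicted division frames: [3, 9, 17, 24, 32, 42, 50, 59, 68, 78, 88, 97, 110, 120, 132]
  true RLS 15 vs predicted RLS 15
  predicted cell-cycle gaps (frames): [6, 8, 7, 8, 10, 8, 9, 9, 10, 10, 9, 13, 10, 12]
```

Every true bud emergence on the unseen cell is recovered within one frame,
so the predicted lifespan (15 divisions) matches the ground truth exactly;
the widening gaps (6 → 12 frames, i.e. 90 min → 3 h) are the late-life
cell-cycle lengthening expected of replicatively aging cells. The other
examples generate fixture datasets (`01`), pretrain and inspect the MAE
against a no-learning baseline (`02`), and score event timelines with the
Hungarian matcher and lifespan statistics (`04`).

A `budscan` command-line tool mirrors the pipeline stages
(`simulate`, `pretrain`, `train`, `predict`, `evaluate`, `run`, `config`);
run `budscan --help` for the subcommands and `budscan config` for all
defaults as YAML.

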