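# Methods

## Model

The unit of inference is an RCM stack: `N` grayscale en-face slices
(`2 ≤ N ≤ 101` supported, up to 71 consumed per stack) acquired at one
lateral position, ordered shallow→deep with a fixed axial step in µm.
Each slice carries one ordinal label, epidermis (0) < DEJ (1) < dermis (2);
stratum-corneum labels are merged into epidermis on ingest. The central
assumption is anatomical: labels down a healthy or lesional stack never
move back up the ordering, and never skip the junction zone, so the four
adjacent-slice transitions epidermis→dermis, DEJ→epidermis,
dermis→epidermis and dermis→DEJ are impossible.

Inference is two-stage, with the stages trained separately:

1. **Slice encoder.** A CNN classifies single slices into the three
   strata. After training, the 3-class head and the nonlinearity on the
   penultimate fully connected layer (256 units by default) are removed and
   the frozen remainder embeds each slice as `h_n ∈ R^256`. End-to-end
   CNN+RNN training is intentionally unsupported: normalization statistics
   behave badly when a per-image network is replicated across a sequence,
   and frozen features let many sequence models share one encoder. The
   default `tiny_cnn` backbone is three 3×3 conv blocks (8/16/32 channels,
   each ReLU + 2×2 average pooling) plus a fourth 3×3 block and global
   average pooling; `inception_v3_style` swaps the fourth block for
   parallel 1×1/3×3/5×5 branches. Inputs are single-channel in [0, 1]
   (multi-channel sources reduced by channel mean, integers scaled by the
   dtype maximum).

2. **Sequence model (RCN).** A bidirectional GRU (64 units per direction,
   one layer per direction) encodes the embedding sequence. An attention
   stage maps encodings to contexts `h̃_n = Σ_m A[n,m] h_m` with `A`
   row-stochastic; the decoder then walks shallow→deep emitting a
   probability row per slice, consuming at step `n` the concatenation of
   `h̃_n` with the probability row emitted at `n−1` (zeros at the first
   slice). Decoders: a dense layer for the full-sequence, partial-sequence
   and Toeplitz variants; a GRU followed by a dense layer for global
   attention.

### Attention variants

* **Toeplitz** (the interesting one): a single learnable kernel `a` of
  length `2D+1`, constrained to be a convex combiner by taking normalized
  exponentials of free weights — non-negative, summing to one, and
  differentiable for any raw values. Row `n` of `A` carries `a` on columns
  `n−D..n+D`; the map has constant diagonals and zero support outside the
  band, and is applied as a convolution over the encoding sequence. Rows
  clipped by a sequence edge or by padding are renormalized over the
  surviving entries, with one kernel shared between interior and edge
  regimes. `D = 0` reduces `A` to the identity, recovering the
  full-sequence model exactly (verified to 1e-5 in the tests with shared
  weights).
* **Global**: additive scoring `score(n,m) = v·tanh(W1 h_n + W2 h_m)`
  normalized by exponentials over unmasked positions. A literal
  fixed-output-size perceptron from `h_n` cannot emit rows whose length
  varies with the stack, so the standard length-agnostic additive form is
  used; the scoring network is a single 32-unit tanh layer, and `v` is
  zero-initialized so training starts from uniform attention.
* **Full-sequence**: `h̃ = h` (identity attention).
* **Partial-sequence**: the GRU sees only an odd window (default 3)
  centred on the target slice, edge windows replicating the terminal
  slice; the centre encoding is decoded directly.

### Training

Sequences are padded/masked to a 71-slice maximum (longer stacks keep
their first, shallowest 71 slices); padded positions produce zero
encodings, receive zero attention weight, and are excluded from the loss.
The loss is masked per-slice cross-entropy plus an L1 penalty with weight
0.05 on the sum of absolute recurrent weights; optimization is Adam at
learning rate 1e-3, batches of 4 stacks, 10% variational dropout on the
recurrent connections (one mask per sequence and direction), and the
snapshot with the best validation accuracy is returned. The decoder
consumes its own previous-step probabilities during both training and
inference (matching inference-time behaviour); ground-truth teacher
forcing is available behind a config flag. The encoder stage, for which
no canonical recipe exists, defaults to Adam at 5e-3 with the rate halved
after 60% and 85% of 14 epochs, batch 32, and geometric augmentation
(shear/zoom/stretch ±10%, rotation ±10°, both flips) — ranges are package
defaults since only the transform list is canonical. Argmax ties break
toward the lower class index.

All trainable components run on a small reverse-mode autodiff core over
numpy arrays (`rcmstrata._autodiff`), with gradients of every primitive
verified against central differences in the test suite.

## Post-processing and boundaries

`enforce_consistency` applies, in order: a 3-slice running median (removes
isolated outliers), a causal max filter `out[n] = max(in[0..n])`
(inclusive prefix maximum — the inclusive reading keeps already-correct
inputs unchanged and leaves position 0 defined), and a DEJ-bridging step
that relabels the first dermis slice of any surviving direct
epidermis→dermis jump as DEJ. The bridge is needed because monotonicity
alone does not forbid skipping the junction: `[0,0,2,2]` passes both
filters yet contains an impossible transition. With it, the output
provably contains none of the four illegal transitions for every input
(checked exhaustively over all 3^10 length-10 sequences), and the
composition is idempotent.

Median edge handling is asymmetric by design: the shallow edge uses the
nearest full 3-window (slices 0..2) so that a first-slice outlier — which
the causal max would otherwise propagate through the whole stack — gets
voted out, while the deep edge replicates the terminal label, since a
trailing outlier poisons nothing and single-slice dermis tails should
survive.

Boundary depths are the depths of the first slice labelled ≥ DEJ
(epidermis–DEJ) and the first slice labelled dermis (DEJ–dermis),
`depth = origin + index · step`; a stratum absent from the sequence yields
a missing boundary, excluded pairwise (and counted) in MAE computations
rather than guessed. The axial step is a required per-stack input — real
instruments use 1.5–5 µm and the value cannot be inferred from pixels.

## Evaluation conventions

Inconsistencies are counted per adjacent slice pair (one illegal pair =
one error), the finest reading consistent with counting discrete errors;
they are reported for raw argmax output, where they measure how well a
model internalized the depth ordering, and post-processing trivially zeroes
them. Sensitivity/specificity are one-vs-rest per class; a class absent
from the truth reports NaN and is excluded from summaries. Boundary MAE is
computed on post-processed labels. `classification_report` is backed by
scikit-learn's confusion matrix and cross-checked in the tests against an
independent hand-rolled counter.

## Synthetic data

The generator emulates the properties of clinical stacks that the method
actually exploits, not their appearance: three ordered strata with
stratum-specific textures (epidermis: white noise smoothed by an isotropic
Gaussian of ~3 px, emulating rounded cellular blobs; dermis: noise smoothed
by an elongated (5, 0.8) px randomly oriented Gaussian, emulating collagen
streaks), a transitional DEJ rendered as a patchy spatial mixture whose
dermal pixel fraction ramps linearly from 0 at the first DEJ slice to 1 at
the last, multiplicative contrast decay `exp(−0.03·(i−b1))` below the first
boundary (imaging degrades with depth), and additive Gaussian sensor noise
(σ = 0.04). Boundary indices are drawn so expected class fractions are
0.44/0.34/0.22 (epidermis/DEJ/dermis, the balance typical of clinical
collections), stacks are 20–46 slices of 64×64 px at a 3 µm step by
default, and splits are subject-wise so no subject leaks across
train/val/test. All randomness flows from explicit seeds; equal seeds give
bit-identical data.

What this does and does not show: passing tests demonstrate that the
sequence models exploit depth context on data whose ambiguity is
concentrated at boundaries — the realistic failure mode — but say nothing
about speckle statistics, undulating 3-D junction geometry, lesional
morphology or inter-reader label noise, none of which are simulated.
`corrupt_labels` provides a separate label-noise channel (boundary-local
flips across the nearest boundary) for exercising the post-processing in
isolation.

## Problem sizes

The standard study configuration used by the tests and the acceptance
script is 60 stacks / 20 subjects (50/20/30% split), 14 encoder epochs and
30 RCN epochs — sizes at which the two-stage pipeline reliably reaches
~0.95 test accuracy against ~0.83 for the single-slice baseline on one
CPU in a few minutes. The 200-epoch schedule remains the `RCNConfig`
default for larger runs.

## Known limitations

* Under purely boundary-local label noise the consistency heuristic does
  not improve boundary MAE: Monte Carlo over 20,000 noisy stacks shows a
  ~1% MAE increase (+0.03 µm at a 3 µm step), because the median filter
  erodes a true boundary-head slice about as often as it removes a stray,
  and the causal max never moves a first-transition estimate. Its value
  under this noise model is eliminating inconsistencies, not sharpening
  boundaries; the corresponding strict-improvement check in the acceptance
  suite fails and is left failing by design.
* The CNN backbones are desk-scale; nothing prevents plugging a larger
  encoder, but none ships with the package.
* No probability-aware smoothing (e.g. Viterbi over the emitted
  posteriors): the label-domain filters are the method under study.
* DICOM/proprietary instrument formats and mosaic stitching are out of
  scope; stacks enter as multi-page TIFF or image directories.
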