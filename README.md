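# rcmstrata

Skin strata delineation in reflectance confocal microscopy (RCM) stacks
with recurrent convolutional networks and Toeplitz attention.

## The problem

Before acquiring diagnostic mosaics, RCM operators collect a pilot *stack*
— single-field grayscale images at one lateral skin position, stepped in
depth by a few micrometres — and must decide which slices show epidermis,
which the dermal-epidermal junction (DEJ, where most skin cancers
originate), and which dermis. `rcmstrata` automates this per-slice
3-way classification and the extraction of the two boundary depths
(epidermis–DEJ and DEJ–dermis), for researchers building quantitative RCM
acquisition tools.

## The method

Classification is two-stage. A CNN is first trained image-wise on single
slices; its 3-class head and the nonlinearity on the penultimate 256-unit
layer are then removed and the frozen network maps every slice to an
embedding `h_n`. A bidirectional GRU encoder (64 units per direction) runs
over the embedding sequence, an attention stage forms context vectors

    h̃_n = Σ_m A[n, m] · h_m,        A row-stochastic,

and an autoregressive decoder emits a probability row per slice, shallow to
deep, consuming the previous slice's probabilities — so the known depth
ordering epidermis < DEJ < dermis informs every prediction.

The distinctive attention variant is **Toeplitz attention**: a single
learnable convex kernel `a` of length `2D+1` (non-negative, summing to 1,
parameterized by normalized exponentials) placed on the diagonals of `A`,
so `A[n, m]` depends only on the offset `m − n` and vanishes for
`|m − n| > D`. Rows clipped by a sequence edge or padding are renormalized.
`D = 0` makes `A` the identity and recovers the plain full-sequence RCN
exactly. Alternatives provided: global (additive) attention, a
partial-sequence model over 3-slice windows, and the no-attention
full-sequence model.

Predicted label sequences are made anatomically consistent by a 3-slice
median filter followed by a causal max filter (inclusive prefix maximum),
plus a DEJ-bridging step for any surviving direct epidermis→dermis jump;
boundary depths are then the depths of the first DEJ and first dermis
slices. Metrics cover per-slice accuracy with per-class
sensitivity/specificity, counts of the four anatomically impossible
transitions, and boundary mean absolute error in µm.

Everything trainable runs on a small numpy reverse-mode autodiff core
(`rcmstrata._autodiff`), so the package has no deep-learning framework
dependency and trains desk-scale models on one CPU.

## Worked example

```python
import numpy as np
from rcmstrata import (SyntheticDatasetConfig, generate_dataset,
                       EncoderConfig, build_encoder, train_encoder,
                       extract_features, RCNConfig, train_rcn,
                       enforce_consistency, extract_boundaries)
from rcmstrata.sequence_models import RCN
from rcmstrata.slice_encoder import classify_images

ds = generate_dataset(SyntheticDatasetConfig(n_stacks=60, subjects=20, seed=14))
arr = lambda s: (np.concatenate([ds.stacks[i].slices for i in ds.split(s)]),
                 np.concatenate([ds.labels[i].labels for i in ds.split(s)]))
(tr_x, tr_y), (va_x, va_y), (te_x, te_y) = arr("train"), arr("val"), arr("test")

enc_cfg = EncoderConfig(seed=5)
enc, _ = train_encoder(build_encoder(enc_cfg), tr_x, tr_y, va_x, va_y, enc_cfg)
print("single-slice test accuracy:",
      (classify_images(enc, te_x) == te_y).mean())

pairs = {s: [(extract_features(enc, ds.stacks[i]), ds.labels[i])
             for i in ds.split(s)] for s in ("train", "val", "test")}
cfg = RCNConfig(variant="toeplitz", D=1, epochs=30, seed=5)
model, _ = train_rcn(RCN(cfg), pairs["train"], pairs["val"], cfg)
correct = total = 0
for feats, lab in pairs["test"]:
    res = model.predict_stack(feats)
    correct += (res.labels == lab.labels[:len(res.labels)]).sum()
    total += len(res.labels)
print("Toeplitz D=1 test accuracy:", correct / total)

res = model.predict_stack(pairs["test"][0][0])
b = extract_boundaries(enforce_consistency(res.labels), axial_step_um=3.0)
print("boundaries (um):", b.epi_dej_um, b.dej_derm_um)
```

With these seeds the pipeline prints a single-slice test accuracy of
`0.828` and a Toeplitz `D=1` sequence-model accuracy of `0.949` — the
sequence model resolves the boundary-adjacent slices that a single-image
classifier cannot — and boundary depths `45.0` and `72.0` µm for the first
test stack (whose true boundaries lie at 42 and 78 µm), the depths of its
first DEJ and first dermis slice.

The same workflow is available from the shell:

```bash
rcmstrata simulate -o data --n-stacks 60 --seed 7
rcmstrata train    --data data -o ckpt --stage encoder --seed 7
rcmstrata train    --data data -o ckpt --stage rcn --variant toeplitz --D 1 --seed 7
rcmstrata predict  --data data --checkpoints ckpt -o predictions.csv
rcmstrata evaluate --data data --predictions predictions.csv -o report.json
```

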