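"""Per-slice convolutional classifier and frozen feature extractor.

Training is two-stage throughout the package: a CNN is first trained to
classify individual slices as epidermis / DEJ / dermis, then its 3-class
head and the nonlinearity on the penultimate fully connected layer are
dropped and the remaining network, weights frozen, maps every slice to an
embedding vector.  The recurrent sequence models consume those embeddings.
End-to-end CNN+RNN training is deliberately unsupported: time-distributed
batch statistics make it fragile, and frozen features let many sequence
models share one encoder.

The default backbone is a four-block CNN sized for desk-scale CPU training;
an ``inception_v3_style`` backbone with a mixed-kernel branch block is
available for larger inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._autodiff import Tensor, concat
from ._nn import (Adam, Linear, glorot, load_state_dict,
                  masked_cross_entropy, softmax_rows, state_dict)
from .stack_io import RCMStack

__all__ = [
    "AugmentationConfig", "EncoderConfig", "FeatureSequence", "SliceEncoder",
    "build_encoder", "augment_slice", "train_encoder", "extract_features",
    "save_encoder", "load_encoder",
]


@dataclass
class AugmentationConfig:
    """Random geometric augmentation ranges for encoder training.

    Shear/zoom/stretch ranges are fractional (0.1 = +-10%), rotation is in
    degrees.  All transforms are sampled independently each call.
    """

    shear: float = 0.1
    zoom: float = 0.1
    rotate_deg: float = 10.0
    stretch: float = 0.1
    hflip: bool = True
    vflip: bool = True

    @classmethod
    def disabled(cls):
        return cls(shear=0.0, zoom=0.0, rotate_deg=0.0, stretch=0.0,
                   hflip=False, vflip=False)


@dataclass
class EncoderConfig:
    backbone: str = "tiny_cnn"
    embedding_dim: int = 256
    input_channels: int = 1
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    lr: float = 5e-3
    epochs: int = 14
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.embedding_dim < 8:
            raise ValueError("embedding_dim must be >= 8")
        if self.input_channels != 1:
            raise ValueError("encoder accepts single-channel images only")


@dataclass
class FeatureSequence:
    """Per-slice embedding vectors for one stack, in slice order."""

    vectors: np.ndarray
    stack_id: str = ""

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be (n_slices, dim)")
        if not np.isfinite(self.vectors).all():
            raise ValueError("feature vectors must be finite")

    def __len__(self):
        return len(self.vectors)


class SliceEncoder:
    """CNN mapping a 1-channel slice to class probabilities or an embedding.

    Architecture (tiny_cnn): four 3x3 conv blocks with 2x2 average pooling
    after the first three, global average pooling, a linear embedding layer
    (no nonlinearity at extraction time) and a 3-class softmax head.  The
    inception_v3_style backbone replaces the last block by parallel 1x1 /
    3x3 / 5x5 branches concatenated channel-wise.
    """

    N_CLASSES = 3

    def __init__(self, config: EncoderConfig):
        if config.backbone not in ("tiny_cnn", "inception_v3_style"):
            raise ValueError(f"unsupported backbone: {config.backbone!r}")
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = (8, 16, 32)
        self.convs = []
        c_in = 1
        for c_out in ch:
            self.convs.append(self._kern(rng, c_out, c_in, 3))
            c_in = c_out
        if config.backbone == "tiny_cnn":
            self.branches = [self._kern(rng, 32, c_in, 3)]
            feat_ch = 32
        else:
            self.branches = [self._kern(rng, 16, c_in, 1),
                             self._kern(rng, 16, c_in, 3),
                             self._kern(rng, 16, c_in, 5)]
            feat_ch = 48
        rng2 = np.random.default_rng(config.seed + 1)
        self.embed = Linear(rng2, feat_ch, config.embedding_dim)
        self.head = Linear(rng2, config.embedding_dim, self.N_CLASSES)

    @staticmethod
    def _kern(rng, c_out, c_in, k):
        flat = glorot(rng, (c_in * k * k, c_out))
        kern = Tensor(flat.data.T.reshape(c_out, c_in, k, k),
                      requires_grad=True)
        return kern, Tensor(np.zeros(c_out), requires_grad=True)

    # ------------------------------------------------------------------ api
    def forward(self, images: np.ndarray, features_only: bool = False) -> Tensor:
        """Run a batch of (B, H, W) images; returns logits or embeddings.

        At feature-extraction time the penultimate layer is linear (its
        nonlinearity removed along with the classifier head).
        """
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3:
            raise ValueError("expected single-channel (B, H, W) images")
        t = Tensor(x[:, None])          # (B, 1, H, W)
        for kern, b in self.convs:
            t = t.conv2d(kern, b).relu().avgpool2d(2)
        branch_outs = [t.conv2d(k, b).relu() for k, b in self.branches]
        t = branch_outs[0] if len(branch_outs) == 1 else concat(branch_outs, axis=1)
        t = t.mean(axis=(2, 3))          # global average pool -> (B, C)
        emb = self.embed(t)
        if features_only:
            return emb
        return self.head(emb.relu())

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return softmax_rows(self.forward(images)).data

    def params(self) -> dict:
        layers = {}
        for i, (k, b) in enumerate(self.convs):
            layers[f"conv{i}.W"] = k
            layers[f"conv{i}.b"] = b
        for i, (k, b) in enumerate(self.branches):
            layers[f"branch{i}.W"] = k
            layers[f"branch{i}.b"] = b
        layers.update({f"embed.{n}": p for n, p in self.embed.params().items()})
        layers.update({f"head.{n}": p for n, p in self.head.params().items()})
        return layers


def build_encoder(config: EncoderConfig) -> SliceEncoder:
    return SliceEncoder(config)


def augment_slice(image: np.ndarray, rng: np.random.Generator,
                  config: AugmentationConfig) -> np.ndarray:
    """Apply one random shear/zoom/rotate/stretch/flip composition.

    The affine part is composed into a single matrix applied about the
    image center with bilinear interpolation and edge reflection, so a
    configuration with all transforms disabled is an exact identity.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("augment_slice expects a single-channel image")
    mat = np.eye(2)
    if config.rotate_deg > 0:
        th = np.deg2rad(rng.uniform(-config.rotate_deg, config.rotate_deg))
        mat = mat @ np.array([[np.cos(th), -np.sin(th)],
                              [np.sin(th), np.cos(th)]])
    if config.shear > 0:
        s = rng.uniform(-config.shear, config.shear)
        mat = mat @ np.array([[1.0, s], [0.0, 1.0]])
    if config.zoom > 0:
        z = 1.0 + rng.uniform(-config.zoom, config.zoom)
        mat = mat @ (np.eye(2) / z)
    if config.stretch > 0:
        sx = 1.0 + rng.uniform(-config.stretch, config.stretch)
        sy = 1.0 + rng.uniform(-config.stretch, config.stretch)
        mat = mat @ np.diag([1.0 / sy, 1.0 / sx])
    out = img
    if not np.allclose(mat, np.eye(2)):
        center = (np.asarray(img.shape) - 1) / 2.0
        offset = center - mat @ center
        out = ndimage.affine_transform(out, mat, offset=offset, order=1,
                                       mode="reflect")
    if config.hflip and rng.random() < 0.5:
        out = out[:, ::-1]
    if config.vflip and rng.random() < 0.5:
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def train_encoder(encoder: SliceEncoder, train_images: np.ndarray,
                  train_labels: np.ndarray, val_images: np.ndarray,
                  val_labels: np.ndarray, config: EncoderConfig | None = None):
    """Train the slice classifier; returns ``(encoder, history)``.

    Minimizes cross-entropy with Adam over augmented mini-batches and keeps
    the snapshot with the best validation accuracy.  ``history`` is a list
    of dicts with epoch, train_loss and val_accuracy.
    """
    config = config or encoder.config
    train_images = np.asarray(train_images, dtype=np.float64)
    train_labels = np.asarray(train_labels, dtype=np.int64)
    if train_images.size == 0:
        raise ValueError("empty training set")
    if len(np.unique(train_labels)) < 2:
        raise ValueError("training slices must contain at least 2 classes")
    rng = np.random.default_rng(config.seed)
    params = encoder.params()
    opt = Adam(params, lr=config.lr)
    history = []
    best = {"acc": -1.0, "state": state_dict(params)}
    n = len(train_images)
    for epoch in range(config.epochs):
        # step schedule: halve the rate for the last 40% and again for the
        # last 15% of epochs to settle the noisy small-batch endgame
        opt.lr = config.lr * 0.5 ** ((epoch >= 0.6 * config.epochs)
                                     + (epoch >= 0.85 * config.epochs))
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            batch = np.stack([augment_slice(train_images[i], rng,
                                            config.augmentation)
                              for i in idx])
            logits = encoder.forward(batch)
            loss = masked_cross_entropy(logits, train_labels[idx],
                                        np.ones(len(idx), dtype=bool))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_pred = classify_images(encoder, val_images)
        acc = float((val_pred == np.asarray(val_labels)).mean())
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_accuracy": acc})
        if acc > best["acc"]:
            best = {"acc": acc, "state": state_dict(params)}
    load_state_dict(params, best["state"])
    return encoder, history


def classify_images(encoder: SliceEncoder, images: np.ndarray,
                    batch_size: int = 64) -> np.ndarray:
    """Argmax class per image, evaluated in deterministic batches."""
    images = np.asarray(images, dtype=np.float64)
    preds = []
    for lo in range(0, len(images), batch_size):
        logits = encoder.forward(images[lo:lo + batch_size]).data
        preds.append(np.argmax(logits, axis=-1))
    return np.concatenate(preds) if preds else np.empty(0, dtype=np.int64)


def extract_features(encoder: SliceEncoder, stack: RCMStack,
                     batch_size: int = 64) -> FeatureSequence:
    """Frozen-encoder embeddings, one vector per slice in slice order.

    Deterministic: no augmentation or stochastic layers run at extraction
    time and the encoder's weights are not touched.
    """
    outs = []
    for lo in range(0, len(stack), batch_size):
        emb = encoder.forward(stack.slices[lo:lo + batch_size],
                              features_only=True)
        outs.append(emb.data)
    return FeatureSequence(np.concatenate(outs), stack_id=stack.stack_id)


def save_encoder(encoder: SliceEncoder, path) -> None:
    """Save config and weights to one ``.npz`` checkpoint."""
    cfg = encoder.config
    meta = np.array([cfg.embedding_dim, cfg.seed], dtype=np.int64)
    np.savez(path, __backbone__=np.array(cfg.backbone), __meta__=meta,
             **state_dict(encoder.params()))


def load_encoder(path) -> SliceEncoder:
    with np.load(path, allow_pickle=False) as z:
        backbone = str(z["__backbone__"])
        dim, seed = (int(v) for v in z["__meta__"])
        state = {k: z[k] for k in z.files if not k.startswith("__")}
    enc = SliceEncoder(EncoderConfig(backbone=backbone, embedding_dim=dim,
                                     seed=seed))
    load_state_dict(enc.params(), state)
    return enc
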