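"""Recurrent sequence models over frozen per-slice features.

A recurrent convolutional network (RCN) here is a bidirectional GRU encoder
running over the frozen CNN embeddings of a stack, an attention stage
turning encodings h_n into context vectors h~_n, and an autoregressive
decoder emitting a 3-class probability row per slice, shallow to deep, with
the previous slice's probabilities fed back as input.

Four variants:

``full_seq``
    No attention (h~_n = h_n, an identity attention map); fully connected
    decoder.
``partial_seq``
    The encoder sees only a fixed odd-width window of slices centred on the
    target slice; the centre encoding is decoded directly.
``global_attention``
    Row-stochastic attention over the whole sequence, scored additively by
    a small learned network; GRU decoder followed by a dense layer.
``toeplitz``
    Local attention with a single learnable convex kernel of length 2D+1
    applied at every depth, so the N x N attention map has constant
    diagonals (a Toeplitz matrix) and zero support outside |m - n| <= D.
    Fully connected decoder.  D = 0 makes the map an identity matrix and
    recovers the full-sequence RCN exactly.

Rows clipped by a sequence edge or by padding are renormalized over the
surviving kernel entries, preserving the convex-combiner contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat, stack
from ._nn import (Adam, GRUCell, Linear, gather_params, glorot,
                  load_state_dict, masked_cross_entropy, softmax_rows,
                  state_dict)
from .slice_encoder import FeatureSequence
from .stack_io import StrataLabelSequence, pad_and_mask

__all__ = [
    "RCNConfig", "RCN", "EncodingSequence", "AttentionMap", "ContextSequence",
    "PredictionResult", "encode_sequence", "toeplitz_kernel",
    "build_toeplitz_attention_map", "apply_attention",
    "global_attention_scores", "decode", "make_partial_sequences",
    "train_rcn", "save_rcn", "load_rcn",
]

VARIANTS = ("full_seq", "partial_seq", "global_attention", "toeplitz")


@dataclass
class RCNConfig:
    variant: str = "toeplitz"
    D: int = 1                       # toeplitz half-width; support is 2D+1
    neighborhood: int = 3            # partial_seq window (odd)
    gru_hidden: int = 64             # per direction
    bidirectional: bool = True
    recurrent_dropout: float = 0.10
    l1_recurrent: float = 0.05       # L1 penalty on recurrent weight matrices
    lr: float = 1e-3
    batch_stacks: int = 4
    epochs: int = 200
    max_len: int = 71
    feature_dim: int = 256
    attention_hidden: int = 32       # width of the additive scoring network
    teacher_forcing: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if self.neighborhood % 2 == 0 or self.neighborhood < 1:
            raise ValueError("neighborhood must be odd and positive")
        for name in ("recurrent_dropout", "l1_recurrent"):
            v = getattr(self, name)
            if not 0.0 <= v <= (1.0 if name == "recurrent_dropout" else np.inf):
                raise ValueError(f"{name} out of range")

    @property
    def h_dim(self) -> int:
        return self.gru_hidden * (2 if self.bidirectional else 1)


# --------------------------------------------------------------------- types
@dataclass
class EncodingSequence:
    """GRU encodings h_1..h_N (forward/backward states concatenated)."""

    h: np.ndarray                    # (N, h_dim)
    mask: np.ndarray = None          # (N,) bool

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=np.float64)
        if self.mask is None:
            self.mask = np.ones(len(self.h), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class AttentionMap:
    """Row-stochastic N x N map from encodings to contexts."""

    A: np.ndarray

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=np.float64)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("attention map must be square")


@dataclass
class ContextSequence:
    h_tilde: np.ndarray              # (N, h_dim)


@dataclass
class PredictionResult:
    probs: np.ndarray                # (N, 3) row-stochastic
    labels: np.ndarray               # argmax per row (lowest index on ties)
    stack_id: str = ""


# --------------------------------------------------------------------- model
class RCN:
    """One recurrent sequence model; parameters live in autodiff tensors."""

    N_CLASSES = 3

    def __init__(self, config: RCNConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        self.gru_f = GRUCell(rng, c.feature_dim, c.gru_hidden)
        self.gru_b = GRUCell(rng, c.feature_dim, c.gru_hidden) \
            if c.bidirectional else None
        if c.variant == "global_attention":
            self.W1 = glorot(rng, (c.h_dim, c.attention_hidden))
            self.W2 = glorot(rng, (c.h_dim, c.attention_hidden))
            self.v = Tensor(np.zeros(c.attention_hidden), requires_grad=True)
            self.dec_gru = GRUCell(rng, c.h_dim + self.N_CLASSES, c.gru_hidden)
            self.dec_out = Linear(rng, c.gru_hidden, self.N_CLASSES)
        else:
            self.dec_gru = None
            self.dec_out = Linear(rng, c.h_dim + self.N_CLASSES,
                                  self.N_CLASSES)
        if c.variant == "toeplitz":
            # zero raw weights -> uniform convex kernel at initialization
            self.kernel_raw = Tensor(np.zeros(2 * c.D + 1), requires_grad=True)
        else:
            self.kernel_raw = None

    # ------------------------------------------------------------ parameters
    def params(self) -> dict:
        layers = {"gru_f": self.gru_f, "dec_out": self.dec_out}
        if self.gru_b is not None:
            layers["gru_b"] = self.gru_b
        if self.dec_gru is not None:
            layers["dec_gru"] = self.dec_gru
        flat = gather_params(layers)
        if self.config.variant == "global_attention":
            flat.update({"att.W1": self.W1, "att.W2": self.W2, "att.v": self.v})
        if self.kernel_raw is not None:
            flat["att.kernel_raw"] = self.kernel_raw
        return flat

    def recurrent_weights(self):
        cells = [self.gru_f]
        if self.gru_b is not None:
            cells.append(self.gru_b)
        if self.dec_gru is not None:
            cells.append(self.dec_gru)
        return [u for cell in cells for u in cell.recurrent_weights()]

    # -------------------------------------------------------------- encoding
    def _encode_t(self, feats: np.ndarray, mask: np.ndarray,
                  rng: np.random.Generator | None = None) -> Tensor:
        """Batched GRU encoding -> Tensor (B, L, h_dim); padded rows are 0."""
        B, L, _ = feats.shape
        X = Tensor(feats)
        m = mask.astype(float)
        drop = self.config.recurrent_dropout if rng is not None else 0.0

        def run(cell: GRUCell, order):
            rmask = None
            if drop > 0.0:
                keep = (rng.random((B, cell.d_hidden)) >= drop)
                rmask = keep / (1.0 - drop)
            h = Tensor(np.zeros((B, cell.d_hidden)))
            outs = [None] * L
            for t in order:
                x_t = X[:, t, :]
                h_new = cell.step(x_t, h, rmask)
                mt = Tensor(m[:, t:t + 1])
                h = h_new * mt + h * (1.0 - mt)
                outs[t] = h * mt
            return outs

        outs_f = run(self.gru_f, range(L))
        if self.gru_b is None:
            return stack(outs_f, axis=1)
        outs_b = run(self.gru_b, range(L - 1, -1, -1))
        return stack([concat([f, b], axis=1)
                      for f, b in zip(outs_f, outs_b)], axis=1)

    # ------------------------------------------------------------- attention
    def _kernel_t(self) -> Tensor:
        return softmax_rows(self.kernel_raw.reshape(1, -1)).reshape(-1)

    def _toeplitz_map_t(self, kernel: Tensor, L: int,
                        mask: np.ndarray) -> Tensor:
        """Batched Toeplitz attention map (B, L, L) from a convex kernel."""
        D = (kernel.shape[0] - 1) // 2
        rows = []
        for k in range(2 * D + 1):
            S = np.zeros((L, L))
            off = k - D
            idx = np.arange(max(0, -off), min(L, L - off))
            S[idx, idx + off] = 1.0
            rows.append(kernel[k] * Tensor(S))
        U = rows[0]
        for r in rows[1:]:
            U = U + r
        Ub = U.expand_dims(0) * Tensor(mask.astype(float)[:, None, :])
        denom = Ub.sum(axis=-1, keepdims=True) + 1e-12
        return Ub / denom

    def _global_map_t(self, h: Tensor, mask: np.ndarray) -> Tensor:
        """Additive-attention map: score(n, m) = v . tanh(W1 h_n + W2 h_m)."""
        Hp = (h @ self.W1).expand_dims(2)       # (B, L, 1, k)
        Hq = (h @ self.W2).expand_dims(1)       # (B, 1, L, k)
        scores = (Hp + Hq).tanh() @ self.v      # (B, L, L)
        neg = (mask.astype(float)[:, None, :] - 1.0) * 1e9
        return softmax_rows(scores + Tensor(neg))

    def _attention_t(self, h: Tensor, mask: np.ndarray) -> Tensor:
        c = self.config
        if c.variant == "full_seq":
            return h
        if c.variant == "toeplitz":
            A = self._toeplitz_map_t(self._kernel_t(), h.shape[1], mask)
        elif c.variant == "global_attention":
            A = self._global_map_t(h, mask)
        else:
            return h
        return A @ h

    # --------------------------------------------------------------- decoder
    def _decode_t(self, ctx: Tensor, mask: np.ndarray,
                  teacher_onehot: np.ndarray | None = None,
                  rng: np.random.Generator | None = None):
        """Autoregressive decoding shallow -> deep.

        Returns (logits, probs) tensors of shape (B, L, 3).  At step n the
        decoder consumes h~_n concatenated with the probability row it
        emitted at n - 1 (a zero vector at the first slice), or the
        ground-truth one-hot when teacher forcing is active.
        """
        B, L, _ = ctx.shape
        prev = Tensor(np.zeros((B, self.N_CLASSES)))
        dec_h = None
        rmask = None
        if self.dec_gru is not None:
            dec_h = Tensor(np.zeros((B, self.config.gru_hidden)))
            if rng is not None and self.config.recurrent_dropout > 0.0:
                keep = (rng.random((B, self.config.gru_hidden))
                        >= self.config.recurrent_dropout)
                rmask = keep / (1.0 - self.config.recurrent_dropout)
        logit_rows, prob_rows = [], []
        for n in range(L):
            inp = concat([ctx[:, n, :], prev], axis=1)
            if self.dec_gru is not None:
                dec_h = self.dec_gru.step(inp, dec_h, rmask)
                logits = self.dec_out(dec_h)
            else:
                logits = self.dec_out(inp)
            p = softmax_rows(logits)
            logit_rows.append(logits)
            prob_rows.append(p)
            if teacher_onehot is not None:
                prev = Tensor(teacher_onehot[:, n])
            else:
                prev = p
        return stack(logit_rows, axis=1), stack(prob_rows, axis=1)

    # --------------------------------------------------------------- forward
    def forward(self, feats: np.ndarray, mask: np.ndarray,
                rng: np.random.Generator | None = None,
                teacher_onehot: np.ndarray | None = None):
        """Full pass on a padded batch; returns (logits, probs) tensors."""
        if feats.shape[-1] != self.config.feature_dim:
            raise ValueError("feature dimension mismatch with model config")
        if self.config.variant == "partial_seq":
            raise ValueError("partial_seq uses forward_windows")
        h = self._encode_t(feats, mask, rng)
        ctx = self._attention_t(h, mask)
        return self._decode_t(ctx, mask, teacher_onehot, rng)

    def forward_windows(self, windows: np.ndarray,
                        rng: np.random.Generator | None = None):
        """Partial-sequence pass: (M, N, d) windows -> (M, 3) for centres."""
        M, N, _ = windows.shape
        mask = np.ones((M, N), dtype=bool)
        h = self._encode_t(windows, mask, rng)
        center = h[:, N // 2, :]
        prev = Tensor(np.zeros((M, self.N_CLASSES)))
        logits = self.dec_out(concat([center, prev], axis=1))
        return logits, softmax_rows(logits)

    # ------------------------------------------------------------- inference
    def predict_stack(self, features: FeatureSequence) -> PredictionResult:
        """Deterministic per-slice probabilities for one stack."""
        feats = features.vectors
        n = len(feats)
        if n > self.config.max_len:
            feats = feats[:self.config.max_len]
            n = len(feats)
        if self.config.variant == "partial_seq":
            windows = make_partial_sequences(
                feats, neighborhood=self.config.neighborhood)
            _, probs = self.forward_windows(windows)
            p = probs.data
        else:
            batch = feats[None]
            mask = np.ones((1, n), dtype=bool)
            _, probs = self.forward(batch, mask)
            p = probs.data[0]
        return PredictionResult(probs=p, labels=np.argmax(p, axis=1),
                                stack_id=features.stack_id)


# --------------------------------------------------- functional (public) api
def encode_sequence(model: RCN, features, mask=None) -> EncodingSequence:
    """Encode one feature sequence (deterministic, no dropout)."""
    feats = np.asarray(getattr(features, "vectors", features), dtype=np.float64)
    if mask is None:
        mask = np.ones(len(feats), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    h = model._encode_t(feats[None], mask[None])
    return EncodingSequence(h.data[0], mask)


def toeplitz_kernel(raw_weights) -> np.ndarray:
    """Convex kernel from free weights via normalized exponentials."""
    raw = np.asarray(raw_weights, dtype=np.float64)
    if raw.ndim != 1 or raw.size % 2 == 0:
        raise ValueError("raw weights must be a 1-D vector of odd length")
    e = np.exp(raw - raw.max())
    return e / e.sum()


def build_toeplitz_attention_map(a, N: int, D: int,
                                 mask=None) -> AttentionMap:
    """Place a convex kernel on the diagonals of an N x N map.

    Interior row n carries the kernel on columns n-D..n+D; rows clipped by
    an edge or by masked columns are renormalized over the surviving
    entries.  D = 0 yields the identity matrix.
    """
    a = np.asarray(a, dtype=np.float64)
    if a.size != 2 * D + 1:
        raise ValueError("kernel length must be 2D+1")
    if mask is None:
        mask = np.ones(N, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    A = np.zeros((N, N))
    for n in range(N):
        lo, hi = max(0, n - D), min(N, n + D + 1)
        cols = np.arange(lo, hi)
        w = a[cols - n + D] * mask[cols]
        s = w.sum()
        if s > 0:
            A[n, cols] = w / s
    return AttentionMap(A)


def apply_attention(attention, encodings) -> ContextSequence:
    """Context vectors h~_n = sum_m A[n, m] h_m."""
    A = attention.A if isinstance(attention, AttentionMap) else np.asarray(attention)
    h = encodings.h if isinstance(encodings, EncodingSequence) else np.asarray(encodings)
    if A.shape[1] != h.shape[0]:
        raise ValueError("attention map and encodings disagree on length")
    return ContextSequence(A @ h)


def global_attention_scores(model: RCN, encodings) -> AttentionMap:
    """Row-stochastic additive-attention map for one encoding sequence."""
    enc = encodings if isinstance(encodings, EncodingSequence) \
        else EncodingSequence(np.asarray(encodings))
    A = model._global_map_t(Tensor(enc.h[None]), enc.mask[None])
    return AttentionMap(A.data[0])


def decode(model: RCN, context) -> PredictionResult:
    """Decode a context sequence into per-slice class probabilities."""
    ct = context.h_tilde if isinstance(context, ContextSequence) \
        else np.asarray(context)
    mask = np.ones((1, len(ct)), dtype=bool)
    _, probs = model._decode_t(Tensor(ct[None]), mask)
    p = probs.data[0]
    return PredictionResult(probs=p, labels=np.argmax(p, axis=1))


def make_partial_sequences(features, labels=None, neighborhood: int = 3):
    """Sliding odd-width windows with terminal-slice replication at edges.

    Returns ``(windows, labels)`` when labels are given, else just the
    (L, neighborhood, d) window array; window i is centred on slice i.
    """
    if neighborhood % 2 == 0 or neighborhood < 1:
        raise ValueError("neighborhood must be odd and positive")
    feats = np.asarray(getattr(features, "vectors", features), dtype=np.float64)
    half = neighborhood // 2
    idx = np.clip(np.arange(len(feats))[:, None]
                  + np.arange(-half, half + 1)[None, :], 0, len(feats) - 1)
    windows = feats[idx]
    if labels is None:
        return windows
    lab = np.asarray(getattr(labels, "labels", labels), dtype=np.int64)
    return windows, lab.copy()


# -------------------------------------------------------------------- train
def _l1_term(model: RCN) -> Tensor:
    total = None
    for U in model.recurrent_weights():
        term = U.abs().sum()
        total = term if total is None else total + term
    return total


def train_rcn(model: RCN, train_pairs, val_pairs, config: RCNConfig | None = None):
    """Train a sequence model on (FeatureSequence, StrataLabelSequence) pairs.

    Loss is masked per-slice cross-entropy plus an L1 penalty on the
    recurrent weight matrices.  The snapshot with the best validation
    accuracy is returned together with a per-epoch history
    (train_loss, val_loss, val_accuracy).
    """
    config = config or model.config
    if not val_pairs:
        raise ValueError("a validation set is required for snapshot selection")
    if not train_pairs:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    params = model.params()
    opt = Adam(params, lr=config.lr)
    if config.variant == "partial_seq":
        return _train_partial(model, train_pairs, val_pairs, config, rng, opt,
                              params)

    feats, mask = pad_and_mask([f for f, _ in train_pairs], config.max_len)
    labels = np.zeros(mask.shape, dtype=np.int64)
    for i, (_, lab) in enumerate(train_pairs):
        n = min(len(lab), config.max_len)
        labels[i, :n] = lab.labels[:n]
    onehot = np.eye(RCN.N_CLASSES)[labels]
    n_seq = len(train_pairs)
    history = []
    best = {"acc": -1.0, "state": state_dict(params)}
    for epoch in range(config.epochs):
        order = rng.permutation(n_seq)
        losses = []
        for lo in range(0, n_seq, config.batch_stacks):
            idx = order[lo:lo + config.batch_stacks]
            bmask = mask[idx]
            L = int(bmask.any(axis=0).sum())      # trim shared tail padding
            bf, bm = feats[idx, :L], bmask[:, :L]
            bl = labels[idx, :L]
            teach = onehot[idx, :L] if config.teacher_forcing else None
            logits, _ = model.forward(bf, bm, rng=rng, teacher_onehot=teach)
            loss = masked_cross_entropy(logits, bl, bm)
            if config.l1_recurrent > 0:
                loss = loss + config.l1_recurrent * _l1_term(model)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_loss, val_acc = _validate(model, val_pairs, config)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": val_loss, "val_accuracy": val_acc})
        if val_acc > best["acc"]:
            best = {"acc": val_acc, "state": state_dict(params)}
    load_state_dict(params, best["state"])
    return model, history


def _train_partial(model, train_pairs, val_pairs, config, rng, opt, params):
    windows, labels = [], []
    for f, lab in train_pairs:
        w, l = make_partial_sequences(f, lab, config.neighborhood)
        windows.append(w)
        labels.append(l)
    windows = np.concatenate(windows)
    labels = np.concatenate(labels)
    n = len(windows)
    batch = max(config.batch_stacks * 8, 8)
    history = []
    best = {"acc": -1.0, "state": state_dict(params)}
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, batch):
            idx = order[lo:lo + batch]
            logits, _ = model.forward_windows(windows[idx], rng=rng)
            loss = masked_cross_entropy(logits, labels[idx],
                                        np.ones(len(idx), dtype=bool))
            if config.l1_recurrent > 0:
                loss = loss + config.l1_recurrent * _l1_term(model)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_loss, val_acc = _validate(model, val_pairs, config)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": val_loss, "val_accuracy": val_acc})
        if val_acc > best["acc"]:
            best = {"acc": val_acc, "state": state_dict(params)}
    load_state_dict(params, best["state"])
    return model, history


def _validate(model: RCN, pairs, config: RCNConfig):
    correct = total = 0
    nll = []
    for f, lab in pairs:
        res = model.predict_stack(f)
        n = min(len(lab), len(res.labels))
        truth = lab.labels[:n]
        correct += int((res.labels[:n] == truth).sum())
        total += n
        nll.append(-np.log(np.maximum(
            res.probs[np.arange(n), truth], 1e-12)).mean())
    return float(np.mean(nll)), float(correct / max(total, 1))


# --------------------------------------------------------------- checkpoints
_CFG_FIELDS = ("variant", "D", "neighborhood", "gru_hidden", "bidirectional",
               "recurrent_dropout", "l1_recurrent", "lr", "batch_stacks",
               "epochs", "max_len", "feature_dim", "attention_hidden",
               "teacher_forcing", "seed")


def save_rcn(model: RCN, path) -> None:
    cfg = {f: getattr(model.config, f) for f in _CFG_FIELDS}
    np.savez(path, __config__=np.array(repr(cfg)),
             **state_dict(model.params()))


def load_rcn(path) -> RCN:
    import ast
    with np.load(path, allow_pickle=False) as z:
        cfg = ast.literal_eval(str(z["__config__"]))
        state = {k: z[k] for k in z.files if k != "__config__"}
    model = RCN(RCNConfig(**cfg))
    load_state_dict(model.params(), state)
    return model
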