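"""Neural-network building blocks on top of the autodiff core.

Layers hold their parameters as named :class:`Tensor` objects; a model is a
dict of layers whose parameters are gathered into a flat ``{name: Tensor}``
mapping for the optimizer and for (de)serialization via ``npz`` files.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat

__all__ = [
    "glorot", "Linear", "GRUCell", "Adam",
    "softmax_rows", "log_softmax_rows", "masked_cross_entropy",
    "gather_params", "state_dict", "load_state_dict",
]


def glorot(rng: np.random.Generator, shape) -> Tensor:
    """Glorot/Xavier-uniform initialization."""
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Linear:
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int):
        self.W = glorot(rng, (d_in, d_out))
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def params(self):
        return {"W": self.W, "b": self.b}


class GRUCell:
    """Gated recurrent unit: z/r gates and candidate state.

    Update rule (Cho et al. convention, as in Keras):
        z_t = sigma(x W_z + h U_z + b_z)
        r_t = sigma(x W_r + h U_r + b_r)
        c_t = tanh(x W_c + (r_t * h) U_c + b_c)
        h_t = z_t * h + (1 - z_t) * c_t

    ``recurrent_mask`` implements dropout on the recurrent connections: a
    single mask per sequence scales ``h`` entering the gates (the Gal &
    Ghahramani variational scheme).  The recurrent matrices U_* are exposed
    for L1 regularization.
    """

    def __init__(self, rng: np.random.Generator, d_in: int, d_hidden: int):
        self.Wz = glorot(rng, (d_in, d_hidden))
        self.Wr = glorot(rng, (d_in, d_hidden))
        self.Wc = glorot(rng, (d_in, d_hidden))
        self.Uz = glorot(rng, (d_hidden, d_hidden))
        self.Ur = glorot(rng, (d_hidden, d_hidden))
        self.Uc = glorot(rng, (d_hidden, d_hidden))
        self.bz = Tensor(np.zeros(d_hidden), requires_grad=True)
        self.br = Tensor(np.zeros(d_hidden), requires_grad=True)
        self.bc = Tensor(np.zeros(d_hidden), requires_grad=True)
        self.d_hidden = d_hidden

    def step(self, x: Tensor, h: Tensor,
             recurrent_mask: np.ndarray | None = None) -> Tensor:
        hd = h if recurrent_mask is None else h * Tensor(recurrent_mask)
        z = (x @ self.Wz + hd @ self.Uz + self.bz).sigmoid()
        r = (x @ self.Wr + hd @ self.Ur + self.br).sigmoid()
        c = (x @ self.Wc + (r * hd) @ self.Uc + self.bc).tanh()
        return z * h + (1.0 - z) * c

    def recurrent_weights(self):
        return [self.Uz, self.Ur, self.Uc]

    def params(self):
        return {k: getattr(self, k)
                for k in ("Wz", "Wr", "Wc", "Uz", "Ur", "Uc", "bz", "br", "bc")}


class Adam:
    def __init__(self, params: dict, lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = dict(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)


def softmax_rows(x: Tensor) -> Tensor:
    """Softmax over the last axis (row max subtracted for stability)."""
    z = x - Tensor(x.data.max(axis=-1, keepdims=True))
    e = z.exp()
    return e / e.sum(axis=-1, keepdims=True)


def log_softmax_rows(x: Tensor) -> Tensor:
    z = x - Tensor(x.data.max(axis=-1, keepdims=True))
    return z - z.exp().sum(axis=-1, keepdims=True).log()


def masked_cross_entropy(logits: Tensor, labels: np.ndarray,
                         mask: np.ndarray) -> Tensor:
    """Mean negative log-likelihood over positions where ``mask`` is true.

    ``logits``: (..., n_classes); ``labels``: integer array matching the
    leading shape; padded positions contribute nothing.
    """
    ls = log_softmax_rows(logits)
    onehot = np.eye(logits.shape[-1])[labels]
    m = mask.astype(float)
    picked = (ls * Tensor(onehot)).sum(axis=-1)
    return -(picked * Tensor(m)).sum() / float(max(m.sum(), 1.0))


def gather_params(layers: dict) -> dict:
    """Flatten ``{layer_name: layer}`` into ``{layer_name.param: Tensor}``."""
    out = {}
    for lname, layer in layers.items():
        if isinstance(layer, Tensor):
            out[lname] = layer
        else:
            for pname, p in layer.params().items():
                out[f"{lname}.{pname}"] = p
    return out


def state_dict(params: dict) -> dict:
    return {k: p.data.copy() for k, p in params.items()}


def load_state_dict(params: dict, state: dict) -> None:
    for k, p in params.items():
        arr = np.asarray(state[k])
        if arr.shape != p.data.shape:
            raise ValueError(f"shape mismatch for parameter {k!r}: "
                             f"{arr.shape} vs {p.data.shape}")
        p.data = arr.astype(np.float64).copy()
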