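"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` replays them in reverse topological order to
accumulate gradients.  Only the operations needed by the slice encoder and
the recurrent sequence models are provided (dense/batched matmul, 2-D
convolution via sliding windows, elementwise nonlinearities, reductions,
slicing, concatenation).  Shapes follow numpy broadcasting; gradients of
broadcast operands are summed back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, parents=parents if req else (),
                      backward=backward if req else None)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            pending = [p for p in node._parents
                       if p.requires_grad and id(p) not in seen]
            if pending:
                stack_.extend(pending)
            else:
                seen.add(id(node))
                topo.append(stack_.pop())
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def bwd(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def bwd(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                      other.data.shape))

        return self._make(out_data, (self, other), bwd)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def bwd(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:          # inner product
                self._accum(g * b)
                other._accum(g * a)
                return
            if a.ndim == 1:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.outer(a, g) if b.ndim == 2 else a[:, None] * g[..., None, :]
            elif b.ndim == 1:
                ga = g[..., :, None] * b
                gb = np.swapaxes(a, -1, -2) @ g[..., None]
                gb = gb[..., 0]
            else:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        return self._make(out_data, (self, other), bwd)

    # ----------------------------------------------------------- elementwise
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accum(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), bwd)

    def abs(self):
        sign = np.sign(self.data)

        def bwd(g):
            self._accum(g * sign)

        return self._make(np.abs(self.data), (self,), bwd)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # --------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def bwd(g):
            self._accum(g.reshape(orig))

        return self._make(self.data.reshape(shape), (self,), bwd)

    def swapaxes(self, a, b):
        def bwd(g):
            self._accum(np.swapaxes(g, a, b))

        return self._make(np.swapaxes(self.data, a, b), (self,), bwd)

    def expand_dims(self, axis):
        def bwd(g):
            self._accum(np.squeeze(g, axis=axis))

        return self._make(np.expand_dims(self.data, axis), (self,), bwd)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bwd(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return self._make(out_data, (self,), bwd)

    # ---------------------------------------------------------- convolutions
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None):
        """Same-padding stride-1 2-D convolution.

        ``self``: (B, C, H, W); ``weight``: (O, C, k, k) with odd k;
        ``bias``: (O,).  Output: (B, O, H, W).
        """
        x, w = self.data, weight.data
        k = w.shape[-1]
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        out_data = np.einsum("bchwuv,ocuv->bohw", win, w, optimize=True)
        if bias is not None:
            out_data = out_data + bias.data[None, :, None, None]

        def bwd(g):
            if weight.requires_grad:
                weight._accum(np.einsum("bchwuv,bohw->ocuv", win, g, optimize=True))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                gp = np.pad(g, ((0, 0), (0, 0), (k - 1, k - 1), (k - 1, k - 1)))
                gwin = np.lib.stride_tricks.sliding_window_view(gp, (k, k), axis=(2, 3))
                w_flip = w[:, :, ::-1, ::-1]
                dxp = np.einsum("bohwuv,ocuv->bchw", gwin, w_flip, optimize=True)
                self._accum(dxp[:, :, p:p + x.shape[2], p:p + x.shape[3]]
                            if p else dxp)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return self._make(out_data, parents, bwd)

    def avgpool2d(self, factor: int = 2):
        b, c, h, w = self.data.shape
        if h % factor or w % factor:
            raise ValueError("spatial dims must be divisible by pool factor")
        r = self.data.reshape(b, c, h // factor, factor, w // factor, factor)
        out_data = r.mean(axis=(3, 5))

        def bwd(g):
            gg = g[:, :, :, None, :, None] / (factor * factor)
            self._accum(np.broadcast_to(
                gg, (b, c, h // factor, factor, w // factor, factor)
            ).reshape(b, c, h, w).copy())

        return self._make(out_data, (self,), bwd)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accum(g[tuple(idx)])

    req = any(t.requires_grad for t in tensors)
    return Tensor(out_data, requires_grad=req,
                  parents=tuple(tensors) if req else (),
                  backward=bwd if req else None)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bwd(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))

    req = any(t.requires_grad for t in tensors)
    return Tensor(out_data, requires_grad=req,
                  parents=tuple(tensors) if req else (),
                  backward=bwd if req else None)
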