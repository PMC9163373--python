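"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the text classifiers in this package: broadcasted
arithmetic, batched matmul, relu/sigmoid/exp/log, softmax, axis reductions
(sum/mean/max), reshape/transpose/concat, embedding lookup and a sliding
window unfold for 1-D convolutions.  Gradients are checked against central
finite differences in the test suite (under float64; training defaults to
float32 for speed).  Gradients are only materialized for tensors that
require them or depend on one that does.
"""
from __future__ import annotations

import numpy as np

_DTYPE = np.float32


def set_dtype(dtype) -> None:
    """Set the global compute dtype (float32 default; float64 for grad checks)."""
    global _DTYPE
    _DTYPE = np.dtype(dtype).type


def get_dtype():
    return _DTYPE


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _tracked(t: "Tensor") -> bool:
    return t.requires_grad or bool(t._prev)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = lambda g: None
        self._prev = _prev

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            # copy: g may alias another node's gradient buffer
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    # ------------------------------------------------------------------ core
    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in seen and _tracked(child):
                    stack.append((child, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            node._backward(node.grad)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, False, (self, other))

        def back(g):
            if _tracked(self):
                self._accum(_unbroadcast(g, self.data.shape))
            if _tracked(other):
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, False, (self, other))

        def back(g):
            if _tracked(self):
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if _tracked(other):
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = back
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, False, (self,))

        def back(g):
            if _tracked(self):
                self._accum(g * exponent * self.data ** (exponent - 1.0))

        out._backward = back
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data), False, (self, other))

        def back(g):
            if _tracked(self):
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if _tracked(other):
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = back
        return out

    __matmul__ = matmul

    # ----------------------------------------------------------- elementwise
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), False, (self,))

        def back(g):
            if _tracked(self):
                self._accum(g * (self.data > 0))

        out._backward = back
        return out

    def sigmoid(self):
        y = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.clip(self.data, None, 80))),
            np.exp(np.clip(self.data, -80, None))
            / (1.0 + np.exp(np.clip(self.data, -80, None))),
        ).astype(self.data.dtype)
        out = Tensor(y, False, (self,))

        def back(g):
            if _tracked(self):
                self._accum(g * y * (1.0 - y))

        out._backward = back
        return out

    def exp(self):
        y = np.exp(np.clip(self.data, -80, 80))
        out = Tensor(y, False, (self,))

        def back(g):
            if _tracked(self):
                self._accum(g * y)

        out._backward = back
        return out

    def log(self):
        out = Tensor(np.log(self.data), False, (self,))

        def back(g):
            if _tracked(self):
                self._accum(g / self.data)

        out._backward = back
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), False, (self,))

        def back(g):
            if not _tracked(self):
                return

            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int):
        """Max along one axis; ties send the gradient to the first maximum."""
        idx = np.argmax(self.data, axis=axis)
        picked = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis)
        out = Tensor(picked.squeeze(axis), False, (self,))

        def back(g):
            if not _tracked(self):
                return
            buf = np.zeros_like(self.data)
            np.put_along_axis(
                buf, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis
            )
            self._accum(buf)

        out._backward = back
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        np.exp(z, out=z)
        z /= z.sum(axis=axis, keepdims=True)
        out = Tensor(z, False, (self,))

        def back(g):
            if not _tracked(self):
                return
            gy = g * z
            inner = gy.sum(axis=axis, keepdims=True)
            gy -= inner * z
            self._accum(gy)

        out._backward = back
        return out

    # --------------------------------------------------------------- shaping
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), False, (self,))

        def back(g):
            if _tracked(self):
                self._accum(g.reshape(self.data.shape))

        out._backward = back
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), False, (self,))
        inv = np.argsort(axes)

        def back(g):
            if _tracked(self):
                self._accum(g.transpose(*inv))

        out._backward = back
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], False, (self,))

        def back(g):
            if not _tracked(self):
                return
            buf = np.zeros_like(self.data)
            np.add.at(buf, key, g)
            self._accum(buf)

        out._backward = back
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), False, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        pieces = np.split(g, splits, axis=axis)
        for t, g in zip(tensors, pieces):
            if _tracked(t):
                t._accum(g)

    out._backward = back
    return out


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``weight[ids]`` with scatter-add backward."""
    out = Tensor(weight.data[ids], False, (weight,))

    def back(g):
        if not _tracked(weight):
            return
        buf = np.zeros_like(weight.data)
        np.add.at(buf, ids, g)
        weight._accum(buf)

    out._backward = back
    return out


def unfold(x: Tensor, width: int) -> Tensor:
    """Sliding windows along the token axis: (B, L, D) -> (B, L-width+1, width*D)."""
    B, L, D = x.data.shape
    if L < width:
        raise ValueError(f"sequence length {L} shorter than kernel width {width}")
    win = np.lib.stride_tricks.sliding_window_view(x.data, width, axis=1)
    # win: (B, L-w+1, D, w) -> (B, L-w+1, w, D) -> flat
    y = win.transpose(0, 1, 3, 2).reshape(B, L - width + 1, width * D)
    out = Tensor(y, False, (x,))

    def back(g):
        if not _tracked(x):
            return
        g = g.reshape(B, L - width + 1, width, D)
        gx = np.zeros_like(x.data)
        for i in range(width):
            gx[:, i : i + L - width + 1, :] += g[:, :, i, :]
        x._accum(gx)

    out._backward = back
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean per-label binary cross-entropy on raw logits (numerically stable)."""
    t = Tensor(np.asarray(targets))
    # softplus(z) - z*t  ==  max(z,0) - z*t + log(1 + exp(-|z|))
    abs_z = logits.relu() + (-logits).relu()
    loss = logits.relu() - logits * t + ((-abs_z).exp() + 1.0).log()
    return loss.mean()
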