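"""Neural building blocks: linear, embedding, layer norm, self-attention,
transformer block and a multi-width 1-D convolution bank."""
from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, concat, embedding, unfold


class Module:
    """Base class tracking named parameters for optimizers and (de)serialization."""

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.named_parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{key}.{i}."))
                    elif isinstance(item, Tensor):
                        out[f"{key}.{i}"] = item
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)[:5]}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = state[k].astype(np.float64).copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    scale = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, size=shape)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int, bias: bool = True):
        self.w = Tensor(_glorot(rng, d_in, d_out, (d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.w
        return y + self.b if self.b is not None else y


class Embedding(Module):
    def __init__(self, rng: np.random.Generator, vocab_size: int, dim: int):
        self.weight = Tensor(rng.normal(0.0, 0.02, size=(vocab_size, dim)), requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return embedding(self.weight, ids)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self._eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * ((var + self._eps) ** -0.5) * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    def __init__(self, rng: np.random.Generator, dim: int, n_heads: int):
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by n_heads {n_heads}")
        self.qkv = Linear(rng, dim, 3 * dim)
        self.proj = Linear(rng, dim, dim)
        self._h = n_heads
        self._dh = dim // n_heads

    def __call__(self, x: Tensor, pad_mask: np.ndarray) -> Tensor:
        B, L, D = x.shape
        h, dh = self._h, self._dh
        qkv = self.qkv(x)  # (B, L, 3D)
        q = qkv[:, :, :D].reshape(B, L, h, dh).transpose(0, 2, 1, 3)
        k = qkv[:, :, D : 2 * D].reshape(B, L, h, dh).transpose(0, 2, 1, 3)
        v = qkv[:, :, 2 * D :].reshape(B, L, h, dh).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        bias = np.where(pad_mask[:, None, None, :] > 0, 0.0, -1e9)
        attn = (scores + bias).softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.proj(ctx)


class TransformerBlock(Module):
    """Pre-norm transformer block with a 2x feed-forward expansion."""

    def __init__(self, rng: np.random.Generator, dim: int, n_heads: int, ff_mult: int = 2):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(rng, dim, n_heads)
        self.ln2 = LayerNorm(dim)
        self.ff1 = Linear(rng, dim, ff_mult * dim)
        self.ff2 = Linear(rng, ff_mult * dim, dim)

    def __call__(self, x: Tensor, pad_mask: np.ndarray) -> Tensor:
        x = x + self.attn(self.ln1(x), pad_mask)
        return x + self.ff2(self.ff1(self.ln2(x)).relu())


class ConvBank(Module):
    """Multi-width 1-D convolutions with ReLU and stride one, max-pooled per filter.

    Output = concatenation over ascending kernel widths of the per-filter
    maxima; widths longer than the sequence are skipped (a warning is the
    caller's responsibility) unless ``pad_short`` is set, in which case the
    input is zero-padded up to the width.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        dim: int,
        kernel_widths: tuple[int, ...],
        filters_per_width: int,
    ):
        self.widths = tuple(sorted(kernel_widths))
        self.weights = [
            Tensor(_glorot(rng, w * dim, filters_per_width, (w * dim, filters_per_width)),
                   requires_grad=True)
            for w in self.widths
        ]
        self.biases = [
            Tensor(np.zeros(filters_per_width), requires_grad=True) for _ in self.widths
        ]

    def __call__(self, x: Tensor) -> Tensor:
        L = x.shape[1]
        feats = []
        for w, wt, b in zip(self.widths, self.weights, self.biases):
            if L < w:
                continue
            conv = unfold(x, w) @ wt + b  # (B, L-w+1, F)
            feats.append(conv.relu().max(axis=1))  # (B, F)
        if not feats:
            raise ValueError(f"sequence length {L} shorter than every kernel width {self.widths}")
        return concat(feats, axis=-1)
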