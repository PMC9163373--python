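"""Encoders and output heads for multi-label note classification.

Three encoders project a token sequence to a dense (tokens x dim) matrix:

``small_contextual``
    A randomly initialized 2-layer transformer (token + learned positional
    embeddings, pre-norm blocks) trained end-to-end; the desk-scale default.
``static_vectors``
    A plain trainable embedding table with no context mixing — the
    word-vector baseline.
``pretrained_contextual``
    The same transformer architecture initialized from an external weight
    archive (e.g. distilled from a pretrained Chinese model); requires an
    ``encoder_weights`` file.

Two heads map the matrix to five logits: ``cnn`` applies multi-width 1-D
convolutions with ReLU and stride one, per-filter max pooling over positions
and a fully connected layer; ``fc`` mean-pools tokens and applies a single
fully connected layer.  Sigmoid outputs give per-category probabilities.
"""
from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .layers import ConvBank, Embedding, LayerNorm, Linear, Module, TransformerBlock

PAD_ID = 0
UNK_ID = 1


class Vocabulary:
    """Character-level vocabulary with reserved PAD/UNK ids."""

    def __init__(self, tokens: list[str]):
        self.id_to_token = ["<pad>", "<unk>"] + tokens
        self.token_to_id = {t: i for i, t in enumerate(self.id_to_token)}

    @classmethod
    def build(cls, texts: list[str]) -> "Vocabulary":
        seen: dict[str, int] = {}
        for text in texts:
            for ch in text:
                seen[ch] = seen.get(ch, 0) + 1
        tokens = sorted(seen, key=lambda t: (-seen[t], t))
        return cls(tokens)

    def __len__(self) -> int:
        return len(self.id_to_token)

    def encode(self, text: str, max_length: int) -> list[int]:
        ids = [self.token_to_id.get(ch, UNK_ID) for ch in text[:max_length]]
        return ids

    def to_dict(self) -> dict:
        return {"tokens": self.id_to_token[2:]}

    @classmethod
    def from_dict(cls, d: dict) -> "Vocabulary":
        return cls(list(d["tokens"]))


class ContextualEncoder(Module):
    def __init__(
        self,
        rng: np.random.Generator,
        vocab_size: int,
        dim: int,
        n_layers: int,
        n_heads: int,
        max_len: int,
    ):
        self.tok = Embedding(rng, vocab_size, dim)
        self.pos = Embedding(rng, max_len, dim)
        self.blocks = [TransformerBlock(rng, dim, n_heads) for _ in range(n_layers)]
        self.ln = LayerNorm(dim)

    def __call__(self, ids: np.ndarray, pad_mask: np.ndarray) -> Tensor:
        L = ids.shape[1]
        x = self.tok(ids) + self.pos(np.arange(L)[None, :])
        for block in self.blocks:
            x = block(x, pad_mask)
        return self.ln(x) * Tensor(pad_mask[:, :, None])


class StaticVectorEncoder(Module):
    """Non-contextual token vectors (word2vec-style baseline)."""

    def __init__(self, rng: np.random.Generator, vocab_size: int, dim: int):
        self.tok = Embedding(rng, vocab_size, dim)

    def __call__(self, ids: np.ndarray, pad_mask: np.ndarray) -> Tensor:
        return self.tok(ids) * Tensor(pad_mask[:, :, None])


class CNNHead(Module):
    def __init__(
        self,
        rng: np.random.Generator,
        dim: int,
        kernel_widths: tuple[int, ...],
        filters_per_width: int,
        n_labels: int,
    ):
        self.bank = ConvBank(rng, dim, kernel_widths, filters_per_width)
        self.out = Linear(rng, len(kernel_widths) * filters_per_width, n_labels)

    def __call__(self, x: Tensor, pad_mask: np.ndarray) -> Tensor:
        return self.out(self.bank(x))


class FCHead(Module):
    def __init__(self, rng: np.random.Generator, dim: int, n_labels: int):
        self.out = Linear(rng, dim, n_labels)

    def __call__(self, x: Tensor, pad_mask: np.ndarray) -> Tensor:
        denom = np.maximum(pad_mask.sum(axis=1, keepdims=True), 1.0)
        pooled = x.sum(axis=1) * Tensor(1.0 / denom)
        return self.out(pooled)


class FamilyHistoryNet(Module):
    """Encoder x head composition producing five logits per note."""

    def __init__(self, encoder: Module, head: Module):
        self.encoder = encoder
        self.head = head

    def __call__(self, ids: np.ndarray, pad_mask: np.ndarray) -> Tensor:
        return self.head(self.encoder(ids, pad_mask), pad_mask)


def batch_ids(
    encoded: list[list[int]], max_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pad a list of id sequences into (ids, pad_mask) arrays."""
    L = min(max(len(e) for e in encoded), max_length)
    ids = np.full((len(encoded), L), PAD_ID, dtype=np.int64)
    mask = np.zeros((len(encoded), L), dtype=np.float64)
    for i, e in enumerate(encoded):
        e = e[:L]
        ids[i, : len(e)] = e
        mask[i, : len(e)] = 1.0
    return ids, mask
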