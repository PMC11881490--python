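"""Neural building blocks: linear/embedding/normalization layers, multi-head
self-attention and graph attention convolutions, all on the package's autodiff
engine.

Modules follow a torch-like contract: ``parameters()`` yields trainable
tensors, ``train()``/``eval()`` toggle dropout and batch-norm behaviour, and
``state_dict()``/``load_state_dict()`` round-trip weights as plain arrays.
Stochastic layers (dropout) take an explicit ``numpy.random.Generator`` so
training runs are reproducible from a single seed.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor, concat, gather_rows, segment_sum

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "BatchNorm1d",
    "Dropout",
    "MultiHeadSelfAttention",
    "TransformerBlock",
    "GATConv",
]


class Module:
    """Minimal container with parameter discovery and train/eval modes."""

    def __init__(self) -> None:
        self.training = True

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for key, value in self.__dict__.items():
            name = f"{prefix}{key}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # buffers (running batch-norm statistics) are discovered by attribute name
    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for key, value in self.__dict__.items():
            name = f"{prefix}{key}"
            if isinstance(value, np.ndarray):
                yield name, value
            elif isinstance(value, Module):
                yield from value.named_buffers(f"{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{name}.{i}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({f"buffer:{name}": b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, value in state.items():
            if name.startswith("buffer:"):
                buf = buffers[name[len("buffer:"):]]
                buf[...] = value
            else:
                params[name].data[...] = value


def _init_normal(rng: np.random.Generator, shape, std: float) -> np.ndarray:
    return rng.normal(0.0, std, size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True, init: str = "he"):
        super().__init__()
        if init == "he":
            std = math.sqrt(2.0 / in_dim)
        elif init == "transformer":
            std = 0.02
        else:
            std = math.sqrt(1.0 / in_dim)
        self.weight = Tensor(_init_normal(rng, (in_dim, out_dim), std), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, n_embeddings: int, dim: int, rng: np.random.Generator, std: float = 0.02):
        super().__init__()
        self.weight = Tensor(_init_normal(rng, (n_embeddings, dim), std), requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        from .autodiff import embedding_lookup

        return embedding_lookup(self.weight, ids)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta


class BatchNorm1d(Module):
    """Batch normalization over axis 0; eval mode uses running statistics."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            n = x.shape[0]
            unbiased = var.data[0] * (n / max(n - 1, 1))
            self.running_mean[...] = (1 - self.momentum) * self.running_mean + self.momentum * mu.data[0]
            self.running_var[...] = (1 - self.momentum) * self.running_var + self.momentum * unbiased
            inv = (var + self.eps) ** -0.5
            return centered * inv * self.gamma + self.beta
        centered = x - self.running_mean
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return centered * Tensor(inv) * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        if rng is None:
            raise ValueError("dropout in training mode requires an rng")
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product attention with ``n_heads`` parallel heads.

    Per-head queries, keys and values come from one fused projection; head
    outputs are concatenated and linearly mixed.  A causal variant masks
    strictly-upper-triangular scores so position ``t`` attends only to
    positions ``<= t``.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads != 0:
            raise ValueError(f"embed dim {dim} not divisible by {n_heads} heads")
        self.dim = dim
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng, init="transformer")
        self.proj = Linear(dim, dim, rng, init="transformer")

    def __call__(self, x: Tensor, causal: bool) -> Tensor:
        b, t, d = x.shape
        h, hd = self.n_heads, self.head_dim
        qkv = self.qkv(x)  # (b, t, 3d)
        qkv = qkv.reshape(b, t, 3, h, hd).transpose(2, 0, 3, 1, 4)  # (3, b, h, t, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(hd))  # (b, h, t, t)
        if causal:
            mask = np.triu(np.full((t, t), -1e9), k=1)
            scores = scores + Tensor(mask)
        attn = scores.softmax(axis=-1)
        out = attn @ v  # (b, h, t, hd)
        out = out.transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm block: LN → MHA → residual; LN → GeLU MLP (+dropout) → residual."""

    def __init__(self, dim: int, n_heads: int, dropout: float, rng: np.random.Generator,
                 ffn_mult: int = 4):
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.ln2 = LayerNorm(dim)
        self.fc1 = Linear(dim, ffn_mult * dim, rng, init="transformer")
        self.fc2 = Linear(ffn_mult * dim, dim, rng, init="transformer")
        self.drop = Dropout(dropout)

    def __call__(self, x: Tensor, causal: bool, rng: np.random.Generator | None = None) -> Tensor:
        x = x + self.attn(self.ln1(x), causal=causal)
        h = self.fc2(self.fc1(self.ln2(x)).gelu())
        x = x + self.drop(h, rng)
        return x


class GATConv(Module):
    """Graph attention convolution over an explicit edge list.

    Messages flow source → target along ``edge_index`` (self-loops are the
    caller's responsibility).  Attention logits are LeakyReLU(a_src·h_src +
    a_dst·h_dst), normalized by softmax over each target's incoming edges.
    With ``concat=True`` head outputs are concatenated, otherwise averaged.
    """

    def __init__(self, in_dim: int, out_dim: int, n_heads: int, rng: np.random.Generator,
                 concat: bool = True, leaky_slope: float = 0.2):
        super().__init__()
        self.in_dim, self.out_dim, self.n_heads = in_dim, out_dim, n_heads
        self.concat = concat
        self.leaky_slope = leaky_slope
        std = math.sqrt(2.0 / in_dim)
        self.weight = Tensor(_init_normal(rng, (in_dim, n_heads * out_dim), std), requires_grad=True)
        self.att_src = Tensor(_init_normal(rng, (n_heads, out_dim), std), requires_grad=True)
        self.att_dst = Tensor(_init_normal(rng, (n_heads, out_dim), std), requires_grad=True)
        self.bias = Tensor(np.zeros(n_heads * out_dim if concat else out_dim), requires_grad=True)

    def __call__(self, x: Tensor, edge_index: np.ndarray) -> Tensor:
        n = x.shape[0]
        src, dst = edge_index[0], edge_index[1]
        h = (x @ self.weight).reshape(n, self.n_heads, self.out_dim)  # (n, H, O)
        alpha_src = (h * self.att_src).sum(axis=-1)  # (n, H)
        alpha_dst = (h * self.att_dst).sum(axis=-1)
        logits = (gather_rows(alpha_src, src) + gather_rows(alpha_dst, dst)).leaky_relu(self.leaky_slope)  # (E, H)
        # numerically stable softmax over incoming edges of each target node
        seg_max = np.full((n, self.n_heads), -np.inf)
        np.maximum.at(seg_max, dst, logits.data)
        z = (logits - Tensor(seg_max[dst])).exp()
        denom = segment_sum(z, dst, n)  # (n, H)
        attn = z / gather_rows(denom, dst)  # (E, H)
        messages = gather_rows(h, src) * attn.reshape(len(src), self.n_heads, 1)
        out = segment_sum(messages, dst, n)  # (n, H, O)
        if self.concat:
            out = out.reshape(n, self.n_heads * self.out_dim)
        else:
            out = out.mean(axis=1)
        return out + self.bias
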