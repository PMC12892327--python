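"""Neural-network building blocks (modules, layers, optimizer).

Thin, explicit layers over the autodiff engine: linear maps, MLPs,
embedding tables, layer normalization, multi-head attention and a
post-norm Transformer block, plus Adam. Parameters are ``Tensor``s with
``requires_grad=True`` discovered by recursing over module attributes,
so ``state_dict`` round-trips cover every model in the package.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from ._autodiff import (
    Tensor,
    concat,
    gather_rows,
    matmul,
    relu,
    softmax,
    sqrt,
)
from .exceptions import ConfigurationError


class Module:
    """Base class providing parameter discovery and state round-trips."""

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{prefix}{name}.{i}", item

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: tuple[int, ...] | None = None) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape or (fan_in, fan_out))


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        self.in_dim, self.out_dim = in_dim, out_dim
        self.weight = parameter(glorot(rng, in_dim, out_dim))
        self.bias = parameter(np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = matmul(x, self.weight)
        return y + self.bias if self.bias is not None else y


class MLP(Module):
    """Stack of Linear layers with ReLU between them (none after the last)."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        if len(dims) < 2:
            raise ConfigurationError("MLP needs at least an input and output dim")
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = relu(x)
        return x


class Embedding(Module):
    def __init__(self, n_embeddings: int, dim: int, rng: np.random.Generator,
                 scale: float = 0.1):
        self.table = parameter(rng.normal(0.0, scale, size=(n_embeddings, dim)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return gather_rows(self.table, idx)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = parameter(np.ones(dim))
        self.beta = parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / sqrt(var + self.eps) * self.gamma + self.beta


class MultiHeadAttention(Module):
    """Scaled dot-product attention over a set of vectors.

    Inputs are 2D ``(n, dim)``; an additive mask (``0`` / ``-1e9``) of shape
    ``(n_q, n_kv)`` restricts attention, e.g. to nodes of the same molecule
    in a batched graph.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 kv_dim: int | None = None):
        if dim % n_heads != 0:
            raise ConfigurationError(
                f"attention heads ({n_heads}) must divide the hidden dim ({dim})")
        kv_dim = kv_dim if kv_dim is not None else dim
        self.dim, self.n_heads, self.head_dim = dim, n_heads, dim // n_heads
        self.q_proj = Linear(dim, dim, rng)
        self.k_proj = Linear(kv_dim, dim, rng)
        self.v_proj = Linear(kv_dim, dim, rng)
        self.out_proj = Linear(dim, dim, rng)

    def __call__(self, query: Tensor, key_value: Tensor | None = None,
                 mask: np.ndarray | None = None) -> Tensor:
        if key_value is None:
            key_value = query
        n_q = query.shape[0]
        n_kv = key_value.shape[0]
        h, d = self.n_heads, self.head_dim
        q = self.q_proj(query).reshape(n_q, h, d).transpose(1, 0, 2)
        k = self.k_proj(key_value).reshape(n_kv, h, d).transpose(1, 0, 2)
        v = self.v_proj(key_value).reshape(n_kv, h, d).transpose(1, 0, 2)
        scores = matmul(q, k.transpose(0, 2, 1)) * (1.0 / np.sqrt(d))
        if mask is not None:
            scores = scores + mask[None, :, :]
        attn = softmax(scores, axis=-1)
        out = matmul(attn, v)  # (h, n_q, d)
        out = out.transpose(1, 0, 2).reshape(n_q, self.dim)
        return self.out_proj(out)


class FeedForward(Module):
    """Position-wise FFN with an internal residual: ``x + W2 relu(W1 x)``."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return x + self.fc2(relu(self.fc1(x)))


class TransformerBlock(Module):
    """Post-norm Transformer encoder block (attention -> LN -> FFN -> LN)."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 ff_mult: int = 2):
        self.attn = MultiHeadAttention(dim, n_heads, rng)
        self.ln1 = LayerNorm(dim)
        self.ffn = FeedForward(dim, ff_mult * dim, rng)
        self.ln2 = LayerNorm(dim)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        x = self.ln1(x + self.attn(x, mask=mask))
        return self.ln2(self.ffn(x))


def log_softmax(z: Tensor, axis: int = -1) -> Tensor:
    from ._autodiff import exp, log

    shift = Tensor(z.data.max(axis=axis, keepdims=True))  # constant shift
    s = z - shift
    lse = log(exp(s).sum(axis=axis, keepdims=True)) + shift
    return z - lse


def cosine_rows(a: Tensor, b: Tensor, eps: float = 1e-8) -> Tensor:
    """Row-wise cosine similarity with an epsilon-guarded denominator."""
    num = (a * b).sum(axis=-1)
    na = sqrt((a * a).sum(axis=-1) + eps * eps)
    nb = sqrt((b * b).sum(axis=-1) + eps * eps)
    return num / (na * nb + eps)


def normalize_rows(x: Tensor, eps: float = 1e-8) -> Tensor:
    norm = sqrt((x * x).sum(axis=-1, keepdims=True) + eps * eps)
    return x / (norm + eps)


def mean_rows(xs: list[Tensor]) -> Tensor:
    """Stack 1D tensors into a matrix (for batched heads over pooled vectors)."""
    return concat([x.reshape(1, -1) for x in xs], axis=0)


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
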