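"""Transformer building blocks on the minimal autograd engine.

GPT-2 conventions throughout: pre-norm blocks, tanh-GELU MLP with a 4x
hidden width, weight init N(0, 0.02), rotary positional phases applied to
queries and keys.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

_dropout_rng: np.random.Generator | None = None


def set_dropout_rng(rng: np.random.Generator | None) -> None:
    """Set the generator used by all Dropout layers (training only)."""
    global _dropout_rng
    _dropout_rng = rng


class Module:
    """Tiny module container: parameters discovered by attribute scan."""

    def __init__(self):
        self.training = False

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor):
                out[key] = val
            elif isinstance(val, Module):
                out.update(val.named_parameters(prefix=f"{key}."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Tensor):
                        out[f"{key}.{i}"] = item
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.named_parameters().values())

    def zero_grad(self) -> None:
        for p in self.named_parameters().values():
            p.zero_grad()

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for val in vars(self).values():
            if isinstance(val, Module):
                val.train(mode)
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True,
                 init_std: float = 0.02):
        super().__init__()
        self.W = Tensor(rng.normal(0.0, init_std, size=(d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        if self.b is not None:
            y = y + self.b
        return y


class Embedding(Module):
    def __init__(self, n: int, dim: int, rng: np.random.Generator, init_std: float = 0.02):
        super().__init__()
        self.W = Tensor(rng.normal(0.0, init_std, size=(n, dim)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return ag.embedding(self.W, idx)


class LayerNorm(Module):
    def __init__(self, dim: int):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.layer_norm(x, self.gamma, self.beta)


class Dropout(Module):
    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        if _dropout_rng is None:
            raise RuntimeError("Dropout in training mode requires set_dropout_rng()")
        keep = 1.0 - self.p
        mask = (_dropout_rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


def rotary_cos_sin(positions: np.ndarray, head_dim: int, base: float = 10000.0):
    """cos/sin phase tables for rotary embeddings at integer window positions."""
    half = head_dim // 2
    inv_freq = 1.0 / base ** (np.arange(half) / half)
    ang = np.asarray(positions, dtype=np.float64)[:, None] * inv_freq[None, :]
    ang = np.concatenate([ang, ang], axis=-1)  # (L, head_dim)
    return np.cos(ang).astype(np.float32), np.sin(ang).astype(np.float32)


def _rotate_half(x: Tensor) -> Tensor:
    half = x.shape[-1] // 2
    x1 = x[..., :half]
    x2 = x[..., half:]
    return ag.concat([-x2, x1], axis=-1)


def apply_rotary(x: Tensor, cos: np.ndarray, sin: np.ndarray) -> Tensor:
    """x: (B, H, L, hd); cos/sin: (L, hd) broadcast over batch and heads."""
    return x * Tensor(cos) + _rotate_half(x) * Tensor(sin)


class MultiHeadAttention(Module):
    """Masked multi-head self-attention with rotary q/k phases."""

    def __init__(self, dim: int, n_heads: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError("embed dim must divide by head count")
        if (dim // n_heads) % 2:
            raise ValueError("head dim must be even for rotary phases")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.drop = Dropout(dropout)

    def __call__(self, x: Tensor, mask_bias: np.ndarray, cos: np.ndarray, sin: np.ndarray) -> Tensor:
        B, L, E = x.shape
        H, hd = self.n_heads, self.head_dim
        qkv = self.qkv(x)  # (B, L, 3E)
        qkv = qkv.reshape(B, L, 3, H, hd).transpose(2, 0, 3, 1, 4)  # (3, B, H, L, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        q = apply_rotary(q, cos, sin)
        k = apply_rotary(k, cos, sin)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        scores = scores + Tensor(mask_bias)  # (L, L) broadcast
        attn = ag.softmax(scores, axis=-1)
        out = attn @ v  # (B, H, L, hd)
        out = out.transpose(0, 2, 1, 3).reshape(B, L, E)
        return self.drop(self.proj(out))


class MLP(Module):
    def __init__(self, dim: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        self.fc = Linear(dim, 4 * dim, rng)
        self.proj = Linear(4 * dim, dim, rng)
        self.drop = Dropout(dropout)

    def __call__(self, x: Tensor) -> Tensor:
        return self.drop(self.proj(ag.gelu(self.fc(x))))


class Block(Module):
    """Pre-norm transformer block."""

    def __init__(self, dim: int, n_heads: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, n_heads, dropout, rng)
        self.ln2 = LayerNorm(dim)
        self.mlp = MLP(dim, dropout, rng)

    def __call__(self, x: Tensor, mask_bias: np.ndarray, cos: np.ndarray, sin: np.ndarray) -> Tensor:
        x = x + self.attn(self.ln1(x), mask_bias, cos, sin)
        x = x + self.mlp(self.ln2(x))
        return x
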