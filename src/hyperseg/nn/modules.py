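"""Layer abstractions over the autodiff tensors.

Every module takes an explicit ``numpy.random.Generator`` for weight
initialization so model construction is exactly reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Parameter

__all__ = ["Module", "Linear", "LayerNorm", "Conv2d", "ConvTranspose2d",
           "MultiHeadAttention", "Mlp"]


class Module:
    """Base class: recursive parameter discovery and state (de)serialization."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{key}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 std: float = 0.02, zero_init: bool = False):
        if zero_init:
            w = np.zeros((d_in, d_out))
        else:
            w = rng.normal(0.0, std, (d_in, d_out))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(d_out))

    def forward(self, x):
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x):
        return F.layer_norm(x, self.weight, self.bias, self.eps)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 bias: bool = True, init_std: float | None = None):
        fan_in = (c_in // groups) * k * k
        std = init_std if init_std is not None else np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, std, (c_out, c_in // groups, k, k))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, groups=self.groups)


class ConvTranspose2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0):
        fan_in = c_in * k * k
        self.weight = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_in, c_out, k, k)))
        self.bias = Parameter(np.zeros(c_out))
        self.stride, self.padding = stride, padding

    def forward(self, x):
        return F.conv_transpose2d(x, self.weight, self.bias,
                                  stride=self.stride, padding=self.padding)


class MultiHeadAttention(Module):
    """Dense scaled-dot-product attention, usable for self or cross attention.

    Queries and keys/values may be different token sequences of the same
    width.  ``out_std`` scales the output-projection init; residual branches
    benefit from a small value.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 out_std: float = 0.02):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.heads = heads
        self.dim = dim
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.out = Linear(dim, dim, rng, std=out_std)

    def forward(self, q_tokens, kv_tokens):
        h, d = self.heads, self.dim
        dh = d // h
        tq = q_tokens.shape[-2]
        tk = kv_tokens.shape[-2]
        batch = q_tokens.shape[:-2]

        def split(x, t):
            # (..., T, D) -> (..., h, T, dh)
            x = x.reshape(batch + (t, h, dh))
            return x.swapaxes(-2, -3)

        q = split(self.q(q_tokens), tq)
        k = split(self.k(kv_tokens), tk)
        v = split(self.v(kv_tokens), tk)
        att = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        att = F.softmax(att, axis=-1)
        ctx = att @ v                               # (..., h, Tq, dh)
        ctx = ctx.swapaxes(-2, -3).reshape(batch + (tq, d))
        return self.out(ctx)


class Mlp(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator,
                 out_std: float = 0.02):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng, std=out_std)

    def forward(self, x):
        return self.fc2(F.gelu(self.fc1(x)))
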