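"""Neural layers for the duplex classifier, built on the autograd Tensor.

Weight layout conventions: Linear stores weights as (in, out); the LSTM
packs its four gates (input, forget, cell, output) column-wise into one
(in, 4*units) matrix; attention projects queries/keys/values with one
(d, d) matrix each and splits heads by reshaping.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, concat, softmax


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Module:
    """Tiny parameter-registry base: collects Tensors off attributes."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                out.append(value)
            elif isinstance(value, Module):
                out.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64)


class Embedding(Module):
    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0.0, 0.02, size=(vocab_size, dim)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.weight.take_rows(idx)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Tensor(_glorot(rng, n_in, n_out), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc / ((var + self.eps) ** 0.5)
        return xn * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads != 0:
            raise ValueError(f"embedding dim {dim} not divisible by {n_heads} heads")
        self.dim = dim
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        h, hd = self.n_heads, self.head_dim

        def split(z: Tensor) -> Tensor:  # (b,t,d) -> (b,h,t,hd)
            return z.reshape(b, t, h, hd).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(hd))
        attn = softmax(scores, axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.wo(ctx)


class EncoderBlock(Module):
    """Post-norm transformer encoder block: attention and a position-wise
    feed-forward (4x expansion, ReLU), each wrapped in residual + LayerNorm."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.norm1 = LayerNorm(dim)
        self.ff1 = Linear(dim, 4 * dim, rng)
        self.ff2 = Linear(4 * dim, dim, rng)
        self.norm2 = LayerNorm(dim)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.attn(x))
        x = self.norm2(x + self.ff2(self.ff1(x).relu()))
        return x


class BiLSTM(Module):
    """Bidirectional LSTM returning the concatenated final hidden states
    (forward h_T ; backward h_T), shape (batch, 2*units)."""

    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        self.units = units
        self.fwd = _LSTMCell(n_in, units, rng)
        self.bwd = _LSTMCell(n_in, units, rng)

    def __call__(self, x: Tensor) -> Tensor:
        t = x.shape[1]
        h_fwd = self.fwd.run(x, range(t))
        h_bwd = self.bwd.run(x, range(t - 1, -1, -1))
        return concat([h_fwd, h_bwd], axis=-1)


class _LSTMCell(Module):
    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        self.units = units
        self.wx = Tensor(_glorot(rng, n_in, 4 * units), requires_grad=True)
        self.wh = Tensor(_glorot(rng, units, 4 * units), requires_grad=True)
        bias = np.zeros(4 * units)
        bias[units : 2 * units] = 1.0  # forget-gate bias opens the memory path
        self.bias = Tensor(bias, requires_grad=True)

    def run(self, x: Tensor, order) -> Tensor:
        b = x.shape[0]
        u = self.units
        h = Tensor(np.zeros((b, u)))
        c = Tensor(np.zeros((b, u)))
        for t in order:
            xt = x[:, t, :]
            gates = xt @ self.wx + h @ self.wh + self.bias
            i = gates[:, 0:u].sigmoid()
            f = gates[:, u : 2 * u].sigmoid()
            g = gates[:, 2 * u : 3 * u].tanh()
            o = gates[:, 3 * u : 4 * u].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h


class Dropout:
    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate

    def __call__(self, x: Tensor, rng: np.random.Generator, training: bool) -> Tensor:
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)
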