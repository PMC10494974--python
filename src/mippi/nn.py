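"""Minimal neural-network engine (numpy, hand-written backpropagation).

The classifier needs masked multi-head self-attention, layer
normalization, position-wise feedforward blocks, 1D convolution, pooling
and an Adam optimizer.  This module implements exactly those primitives
with explicit forward/backward passes.  Layers are stateless with
respect to activations: ``forward`` returns ``(output, cache)`` and
``backward(cache, grad_out)`` returns the input gradient while
accumulating parameter gradients, so one layer object can be applied
several times per step (the reference and mutant windows share weights).

Arrays are ``float32`` with shape ``(batch, length, channels)`` unless
noted.  All randomness (initialization, dropout) flows through a
``numpy`` ``Generator`` supplied by the caller, so runs are exactly
reproducible from a seed.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

F32 = np.float32
NEG_INF = F32(-1e9)


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("name", "v", "g")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.v = value.astype(F32)
        self.g = np.zeros_like(self.v)


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = math.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
                   fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _init(rng, shape, fan_in, fan_out, scheme: str) -> np.ndarray:
    if scheme == "he_uniform":
        return he_uniform(rng, shape, fan_in)
    if scheme == "glorot_uniform":
        return glorot_uniform(rng, shape, fan_in, fan_out)
    raise ValueError(f"unknown init scheme: {scheme}")


class Layer:
    """Base class; concrete layers define forward/backward and params."""

    def params(self) -> list[Param]:
        return []


class Dense(Layer):
    def __init__(self, rng, d_in: int, d_out: int, name: str, init: str = "he_uniform"):
        self.W = Param(f"{name}.W", _init(rng, (d_in, d_out), d_in, d_out, init))
        self.b = Param(f"{name}.b", np.zeros(d_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        return x @ self.W.v + self.b.v, x

    def backward(self, cache, grad):
        x = cache
        x2 = x.reshape(-1, x.shape[-1])
        g2 = grad.reshape(-1, grad.shape[-1])
        self.W.g += x2.T @ g2
        self.b.g += g2.sum(axis=0)
        return grad @ self.W.v.T


class Embedding(Layer):
    """Token lookup table; row 0 is the padding/unknown token."""

    def __init__(self, rng, n_tokens: int, d: int, name: str):
        # small normal init, standard for embedding tables
        self.table = Param(f"{name}.table", rng.normal(0.0, 0.05, size=(n_tokens, d)))

    def params(self):
        return [self.table]

    def forward(self, tokens):
        return self.table.v[tokens], tokens

    def backward(self, cache, grad):
        tokens = cache
        np.add.at(self.table.g, tokens.reshape(-1), grad.reshape(-1, grad.shape[-1]))
        return None  # tokens are not differentiable


class ReLU(Layer):
    def forward(self, x):
        mask = x > 0
        return x * mask, mask

    def backward(self, cache, grad):
        return grad * cache


class LayerNorm(Layer):
    def __init__(self, d: int, name: str, eps: float = 1e-5):
        self.gamma = Param(f"{name}.gamma", np.ones(d))
        self.beta = Param(f"{name}.beta", np.zeros(d))
        self.eps = F32(eps)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        return xhat * self.gamma.v + self.beta.v, (xhat, inv)

    def backward(self, cache, grad):
        xhat, inv = cache
        self.gamma.g += (grad * xhat).sum(axis=tuple(range(grad.ndim - 1)))
        self.beta.g += grad.sum(axis=tuple(range(grad.ndim - 1)))
        gx = grad * self.gamma.v
        m1 = gx.mean(axis=-1, keepdims=True)
        m2 = (gx * xhat).mean(axis=-1, keepdims=True)
        return (gx - m1 - xhat * m2) * inv


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x, train: bool):
        if not train or self.p <= 0.0:
            return x, None
        keep = (self.rng.random(x.shape) >= self.p).astype(F32) / F32(1.0 - self.p)
        return x * keep, keep

    def backward(self, cache, grad):
        if cache is None:
            return grad
        return grad * cache


def softmax_lastaxis(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention(Layer):
    """Masked multi-head self-attention; padded keys get -1e9 logits.

    The most recent attention weights are kept on ``last_attention``
    with shape (batch, heads, Lq, Lk) for the interpretability export.
    """

    def __init__(self, rng, d_model: int, n_heads: int, name: str,
                 init: str = "he_uniform"):
        if d_model % n_heads != 0:
            raise ValueError(f"d_model {d_model} not divisible by n_heads {n_heads}")
        self.h = n_heads
        self.dh = d_model // n_heads
        self.Wq = Dense(rng, d_model, d_model, f"{name}.q", init)
        self.Wk = Dense(rng, d_model, d_model, f"{name}.k", init)
        self.Wv = Dense(rng, d_model, d_model, f"{name}.v", init)
        self.Wo = Dense(rng, d_model, d_model, f"{name}.o", init)
        self.last_attention: np.ndarray | None = None

    def params(self):
        return self.Wq.params() + self.Wk.params() + self.Wv.params() + self.Wo.params()

    def _split(self, x):
        B, L, D = x.shape
        return x.reshape(B, L, self.h, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x):
        B, H, L, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, L, H * dh)

    def forward(self, x, mask):
        """``mask`` is (B, L) bool, True on real residues."""
        q, cq = self.Wq.forward(x)
        k, ck = self.Wk.forward(x)
        v, cv = self.Wv.forward(x)
        Q, K, V = self._split(q), self._split(k), self._split(v)
        scale = F32(1.0 / math.sqrt(self.dh))
        scores = (Q @ K.transpose(0, 1, 3, 2)) * scale
        key_mask = mask[:, None, None, :]  # (B,1,1,Lk)
        scores = np.where(key_mask, scores, NEG_INF)
        A = softmax_lastaxis(scores)
        self.last_attention = A
        ctx = A @ V
        merged = self._merge(ctx)
        out, co = self.Wo.forward(merged)
        return out, (cq, ck, cv, co, Q, K, V, A, scale, key_mask)

    def backward(self, cache, grad):
        cq, ck, cv, co, Q, K, V, A, scale, key_mask = cache
        d_merged = self.Wo.backward(co, grad)
        d_ctx = self._split(d_merged)
        dA = d_ctx @ V.transpose(0, 1, 3, 2)
        dV = A.transpose(0, 1, 3, 2) @ d_ctx
        # softmax backward; masked keys have A ~ 0 so they get ~0 gradient
        ds = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        ds = np.where(key_mask, ds, 0.0)
        dQ = (ds @ K) * scale
        dK = (ds.transpose(0, 1, 3, 2) @ Q) * scale
        dx = self.Wq.backward(cq, self._merge(dQ))
        dx += self.Wk.backward(ck, self._merge(dK))
        dx += self.Wv.backward(cv, self._merge(dV))
        return dx


class FeedForward(Layer):
    """Two-layer position-wise feedforward with ReLU."""

    def __init__(self, rng, d_model: int, d_hidden: int, name: str,
                 init: str = "he_uniform"):
        self.fc1 = Dense(rng, d_model, d_hidden, f"{name}.fc1", init)
        self.relu = ReLU()
        self.fc2 = Dense(rng, d_hidden, d_model, f"{name}.fc2", init)

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def forward(self, x):
        h, c1 = self.fc1.forward(x)
        a, cr = self.relu.forward(h)
        y, c2 = self.fc2.forward(a)
        return y, (c1, cr, c2)

    def backward(self, cache, grad):
        c1, cr, c2 = cache
        g = self.fc2.backward(c2, grad)
        g = self.relu.backward(cr, g)
        return self.fc1.backward(c1, g)


class TransformerEncoderBlock(Layer):
    """Self-attention + feedforward, each wrapped in residual + layer norm
    with dropout (post-norm arrangement)."""

    def __init__(self, rng, d_model: int, n_heads: int, ffn_width: int,
                 dropout: float, drop_rng: np.random.Generator, name: str,
                 init: str = "he_uniform"):
        self.attn = MultiHeadSelfAttention(rng, d_model, n_heads, f"{name}.attn", init)
        self.ln1 = LayerNorm(d_model, f"{name}.ln1")
        self.ffn = FeedForward(rng, d_model, ffn_width, f"{name}.ffn", init)
        self.ln2 = LayerNorm(d_model, f"{name}.ln2")
        self.drop1 = Dropout(dropout, drop_rng)
        self.drop2 = Dropout(dropout, drop_rng)

    def params(self):
        return (self.attn.params() + self.ln1.params()
                + self.ffn.params() + self.ln2.params())

    def forward(self, x, mask, train: bool):
        a, ca = self.attn.forward(x, mask)
        a, cd1 = self.drop1.forward(a, train)
        x1, cl1 = self.ln1.forward(x + a)
        f, cf = self.ffn.forward(x1)
        f, cd2 = self.drop2.forward(f, train)
        x2, cl2 = self.ln2.forward(x1 + f)
        return x2, (ca, cd1, cl1, cf, cd2, cl2)

    def backward(self, cache, grad):
        ca, cd1, cl1, cf, cd2, cl2 = cache
        g = self.ln2.backward(cl2, grad)
        gf = self.drop2.backward(cd2, g)
        g = g + self.ffn.backward(cf, gf)
        g = self.ln1.backward(cl1, g)
        ga = self.drop1.backward(cd1, g)
        return g + self.attn.backward(ca, ga)


class Conv1D(Layer):
    """Same-padded 1D convolution along the length axis."""

    def __init__(self, rng, c_in: int, c_out: int, kernel: int, name: str,
                 init: str = "he_uniform"):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.k = kernel
        self.W = Param(f"{name}.W",
                       _init(rng, (kernel, c_in, c_out), kernel * c_in, c_out, init))
        self.b = Param(f"{name}.b", np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        B, L, C = x.shape
        pad = self.k // 2
        xp = np.zeros((B, L + 2 * pad, C), dtype=F32)
        xp[:, pad:pad + L] = x
        y = np.zeros((B, L, self.W.v.shape[2]), dtype=F32)
        for o in range(self.k):
            y += xp[:, o:o + L] @ self.W.v[o]
        y += self.b.v
        return y, xp

    def backward(self, cache, grad):
        xp = cache
        B, Lp, C = xp.shape
        L = grad.shape[1]
        pad = self.k // 2
        g2 = grad.reshape(-1, grad.shape[-1])
        self.b.g += g2.sum(axis=0)
        dxp = np.zeros_like(xp)
        for o in range(self.k):
            self.W.g[o] += xp[:, o:o + L].reshape(-1, C).T @ g2
            dxp[:, o:o + L] += grad @ self.W.v[o].T
        return dxp[:, pad:pad + L]


class MaxPool1D(Layer):
    """Non-overlapping max pooling along length; a trailing remainder is dropped."""

    def __init__(self, pool: int = 2):
        self.p = pool

    def forward(self, x):
        B, L, C = x.shape
        Lt = (L // self.p) * self.p
        xr = x[:, :Lt].reshape(B, Lt // self.p, self.p, C)
        idx = xr.argmax(axis=2)
        y = np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]
        return y, (idx, x.shape)

    def backward(self, cache, grad):
        idx, shape = cache
        B, L, C = shape
        Lt = (L // self.p) * self.p
        dxr = np.zeros((B, Lt // self.p, self.p, C), dtype=F32)
        np.put_along_axis(dxr, idx[:, :, None, :], grad[:, :, None, :], axis=2)
        dx = np.zeros(shape, dtype=F32)
        dx[:, :Lt] = dxr.reshape(B, Lt, C)
        return dx


class ResidualConvBlock(Layer):
    """Two convolutional subblocks with identity skips and max pooling.

    Each subblock is conv -> ReLU -> conv, added to its input (identity
    skip), passed through ReLU and then max-pooled, so one block reduces
    the length axis by a factor of pool^2 while preserving channels.
    """

    def __init__(self, rng, channels: int, kernel: int, pool: int, name: str,
                 init: str = "he_uniform"):
        self.subblocks = []
        for s in range(2):
            conv1 = Conv1D(rng, channels, channels, kernel, f"{name}.sub{s}.conv1", init)
            conv2 = Conv1D(rng, channels, channels, kernel, f"{name}.sub{s}.conv2", init)
            self.subblocks.append((conv1, ReLU(), conv2, ReLU(), MaxPool1D(pool)))

    def params(self):
        out = []
        for conv1, _, conv2, _, _ in self.subblocks:
            out += conv1.params() + conv2.params()
        return out

    def forward(self, x):
        caches = []
        for conv1, relu1, conv2, relu2, pool in self.subblocks:
            h, c1 = conv1.forward(x)
            h, cr1 = relu1.forward(h)
            h, c2 = conv2.forward(h)
            s, cr2 = relu2.forward(h + x)
            x, cp = pool.forward(s)
            caches.append((c1, cr1, c2, cr2, cp))
        return x, caches

    def backward(self, cache, grad):
        for (conv1, relu1, conv2, relu2, pool), (c1, cr1, c2, cr2, cp) in zip(
            reversed(self.subblocks), reversed(cache)
        ):
            g = pool.backward(cp, grad)
            g = relu2.backward(cr2, g)
            gh = conv2.backward(c2, g)
            gh = relu1.backward(cr1, gh)
            gh = conv1.backward(c1, gh)
            grad = g + gh  # skip path + conv path
        return grad


class LSTMLayer(Layer):
    """Single-layer LSTM returning the full hidden-state sequence.

    Used only by the encoder-substitution ablation; backpropagation
    through time is explicit and unoptimized.
    """

    def __init__(self, rng, d_in: int, d_hidden: int, name: str):
        scale = 1.0 / math.sqrt(d_in)
        self.W = Param(f"{name}.W", rng.uniform(-scale, scale, size=(d_in, 4 * d_hidden)))
        self.U = Param(f"{name}.U", rng.uniform(-scale, scale, size=(d_hidden, 4 * d_hidden)))
        self.b = Param(f"{name}.b", np.zeros(4 * d_hidden))
        self.dh = d_hidden

    def params(self):
        return [self.W, self.U, self.b]

    def forward(self, x, mask=None, train: bool = False):
        B, L, _ = x.shape
        H = self.dh
        h = np.zeros((B, H), dtype=F32)
        c = np.zeros((B, H), dtype=F32)
        ys = np.zeros((B, L, H), dtype=F32)
        steps = []
        for t in range(L):
            z = x[:, t] @ self.W.v + h @ self.U.v + self.b.v
            i = 1.0 / (1.0 + np.exp(-z[:, :H]))
            f = 1.0 / (1.0 + np.exp(-z[:, H:2 * H]))
            g = np.tanh(z[:, 2 * H:3 * H])
            o = 1.0 / (1.0 + np.exp(-z[:, 3 * H:]))
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            steps.append((x[:, t], h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
            ys[:, t] = h
        return ys, steps

    def backward(self, cache, grad):
        B, L, H = grad.shape
        dx = np.zeros((B, L, cache[0][0].shape[-1]), dtype=F32)
        dh_next = np.zeros((B, H), dtype=F32)
        dc_next = np.zeros((B, H), dtype=F32)
        for t in reversed(range(L)):
            xt, h_prev, c_prev, i, f, g, o, c_new = cache[t]
            dh = grad[:, t] + dh_next
            tanh_c = np.tanh(c_new)
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c ** 2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g ** 2), do * o * (1 - o)],
                axis=1,
            )
            self.W.g += xt.T @ dz
            self.U.g += h_prev.T @ dz
            self.b.g += dz.sum(axis=0)
            dx[:, t] = dz @ self.W.v.T
            dh_next = dz @ self.U.v.T
        return dx


class GlobalAveragePool(Layer):
    def forward(self, x):
        return x.mean(axis=1), x.shape

    def backward(self, cache, grad):
        B, L, C = cache
        return np.repeat(grad[:, None, :], L, axis=1) / F32(L)


class Adam:
    """Adam optimizer with bias correction, linear warmup and global-norm
    gradient clipping.

    Warmup ramps the step size linearly over ``warmup_steps`` updates;
    post-norm transformer blocks are prone to collapsing their residual
    signal when hit with full-size updates from the start, and a short
    warmup is the standard remedy.
    """

    def __init__(self, params: Sequence[Param], lr: float = 2e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 warmup_steps: int = 0, clip_norm: float = 0.0):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.warmup = warmup_steps
        self.clip_norm = clip_norm
        self.m = [np.zeros_like(p.v) for p in self.params]
        self.v = [np.zeros_like(p.v) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.g[...] = 0.0

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * math.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        if self.warmup > 0 and self.t <= self.warmup:
            lr_t *= self.t / self.warmup
        if self.clip_norm > 0:
            total = math.sqrt(sum(float(np.sum(p.g * p.g)) for p in self.params))
            if total > self.clip_norm:
                scale = F32(self.clip_norm / total)
                for p in self.params:
                    p.g *= scale
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (p.g - m)
            v += (1 - self.b2) * (p.g * p.g - v)
            p.v -= F32(lr_t) * m / (np.sqrt(v) + self.eps)
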