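"""Neural-network building blocks on the autodiff engine.

Initialization follows the usual fan-based uniform scheme (Glorot) from a
module-local generator, so a model's weights are a pure function of its
seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, conv1d_same

__all__ = [
    "Module",
    "Dense",
    "Conv1D",
    "LayerNorm",
    "Dropout",
    "MultiHeadSelfAttention",
    "Sequential",
    "Activation",
]


class Module:
    """Base class: parameter discovery by attribute walk."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for v in vars(self).values():
            items = v if isinstance(v, (list, tuple)) else [v]
            for item in items:
                if isinstance(item, Tensor) and item.requires_grad:
                    if id(item) not in seen:
                        params.append(item)
                        seen.add(id(item))
                elif isinstance(item, Module):
                    for p in item.parameters():
                        if id(p) not in seen:
                            params.append(p)
                            seen.add(id(p))
        return params

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state, strict=True):
            p.data = s.copy()

    def __call__(self, x: Tensor, **kw) -> Tensor:
        return self.forward(x, **kw)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Tensor(_glorot(rng, (n_in, n_out), n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1D(Module):
    """Length-preserving 1-D convolution, (N, L, C_in) -> (N, L, C_out)."""

    def __init__(self, kernel: int, n_in: int, n_out: int, rng: np.random.Generator):
        fan_in, fan_out = kernel * n_in, kernel * n_out
        self.w = Tensor(
            _glorot(rng, (kernel, n_in, n_out), fan_in, fan_out), requires_grad=True
        )
        self.b = Tensor(np.zeros(n_out), requires_grad=True)
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        return conv1d_same(x, self.w, self.b)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; active only when called with training=True."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def parameters(self):
        return []

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        if not training or self.rate <= 0:
            return x
        keep = 1.0 - self.rate
        mask = self.rng.binomial(1, keep, size=x.shape) / keep
        return x * Tensor(mask)


class Activation(Module):
    def __init__(self, name: str):
        self.name = name

    def parameters(self):
        return []

    def forward(self, x: Tensor) -> Tensor:
        return getattr(x, self.name)()


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def parameters(self):
        out = []
        for m in self.mods:
            out.extend(m.parameters())
        return out

    def forward(self, x: Tensor, **kw) -> Tensor:
        for m in self.mods:
            x = m(x, **kw) if isinstance(m, Dropout) else m(x)
        return x


class MultiHeadSelfAttention(Module):
    """Multi-head self-attention over (N, T, D) token sequences."""

    def __init__(self, dim: int, n_heads: int, head_dim: int, rng: np.random.Generator):
        inner = n_heads * head_dim
        self.wq = Dense(dim, inner, rng)
        self.wk = Dense(dim, inner, rng)
        self.wv = Dense(dim, inner, rng)
        self.wo = Dense(inner, dim, rng)
        self.n_heads = n_heads
        self.head_dim = head_dim

    def forward(self, x: Tensor) -> Tensor:
        N, T, _ = x.shape
        H, Dh = self.n_heads, self.head_dim

        def split(t: Tensor) -> Tensor:
            return t.reshape(N, T, H, Dh).transpose(0, 2, 1, 3)  # (N, H, T, Dh)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(Dh))
        attn = scores.softmax(axis=-1)
        ctx = attn @ v  # (N, H, T, Dh)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(N, T, H * Dh)
        return self.wo(ctx)
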