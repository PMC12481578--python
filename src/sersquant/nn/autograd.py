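"""A compact reverse-mode automatic-differentiation engine on numpy.

Only the operations the package's models need are implemented: dense and
1-D convolutional algebra, the usual activations, reductions, reshaping,
concatenation and slicing.  Tensors record a backward closure and the
graph is traversed in reverse topological order.  Gradients broadcast the
numpy way and are summed back to the parameter shape.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "concat", "conv1d_same", "no_grad"]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    # ---- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()
        # break closure cycles so large intermediate buffers free promptly
        for node in topo:
            node._backward = None
            node._parents = ()

    # ---- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self):
        def backward():
            if self.requires_grad:
                self._accum(-out.grad)

        out = self._make(-self.data, (self,), backward)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(
                        -out.grad * self.data / (other.data**2), other.data.shape
                    )
                )

        out = self._make(out_data, (self, other), backward)
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, k: float):
        out_data = self.data**k

        def backward():
            if self.requires_grad:
                self._accum(out.grad * k * self.data ** (k - 1))

        out = self._make(out_data, (self,), backward)
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward():
            if self.requires_grad:
                g = out.grad @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                g = np.swapaxes(self.data, -1, -2) @ out.grad
                other._accum(_unbroadcast(g, other.data.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    # ---- elementwise functions -----------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * out_data)

        out = self._make(out_data, (self,), backward)
        return out

    def log(self):
        def backward():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out = self._make(np.log(self.data), (self,), backward)
        return out

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * 0.5 / out_data)

        out = self._make(out_data, (self,), backward)
        return out

    def abs(self):
        def backward():
            if self.requires_grad:
                self._accum(out.grad * np.sign(self.data))

        out = self._make(np.abs(self.data), (self,), backward)
        return out

    def relu(self):
        mask = self.data > 0

        def backward():
            if self.requires_grad:
                self._accum(out.grad * mask)

        out = self._make(self.data * mask, (self,), backward)
        return out

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * (1.0 - out_data**2))

        out = self._make(out_data, (self,), backward)
        return out

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * out_data * (1.0 - out_data))

        out = self._make(out_data, (self,), backward)
        return out

    def gelu(self):
        """Gaussian error linear unit (tanh approximation)."""
        c = np.sqrt(2.0 / np.pi)
        x = self.data
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out_data = 0.5 * x * (1.0 + t)

        def backward():
            if self.requires_grad:
                dinner = c * (1.0 + 3 * 0.044715 * x**2)
                grad = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * dinner
                self._accum(out.grad * grad)

        out = self._make(out_data, (self,), backward)
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward():
            if self.requires_grad:
                g = out.grad
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accum(out_data * (g - dot))

        out = self._make(out_data, (self,), backward)
        return out

    # ---- reductions & shaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out = self._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def backward():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        out = self._make(out_data, (self,), backward)
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward():
            if self.requires_grad:
                self._accum(out.grad.transpose(inv))

        out = self._make(self.data.transpose(axes), (self,), backward)
        return out

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, key, out.grad)
                self._accum(g)

        out = self._make(out_data, (self,), backward)
        return out


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    out = Tensor(out_data)
    if _GRAD_ENABLED[-1] and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def backward():
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * out_data.ndim
                    sl[axis] = slice(int(a), int(b))
                    t._accum(out.grad[tuple(sl)])

        out._backward = backward
    return out


def conv1d_same(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Length-preserving 1-D convolution (cross-correlation convention).

    ``x``: (N, L, C_in); ``w``: (K, C_in, C_out); ``b``: (C_out,).
    Zero padding splits K-1 as (left = (K-1)//2, right = rest).
    """
    x = Tensor._lift(x)
    w = Tensor._lift(w)
    N, L, Cin = x.data.shape
    K, Cin2, Cout = w.data.shape
    if Cin != Cin2:
        raise ValueError("channel mismatch")
    if L < K:
        raise ValueError("input shorter than kernel")
    pl = (K - 1) // 2
    pr = K - 1 - pl
    xp = np.pad(x.data, ((0, 0), (pl, pr), (0, 0)))
    # patches: (N, L, K, Cin) -> contiguous column matrix for BLAS
    patches = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)
    cols = np.ascontiguousarray(patches.transpose(0, 1, 3, 2)).reshape(N * L, K * Cin)
    wmat = w.data.reshape(K * Cin, Cout)
    out_data = (cols @ wmat).reshape(N, L, Cout)
    if b is not None:
        out_data = out_data + b.data

    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data)
    if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents

        def backward():
            g = out.grad  # (N, L, Cout)
            gflat = g.reshape(N * L, Cout)
            if w.requires_grad:
                w._accum((cols.T @ gflat).reshape(K, Cin, Cout))
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 1)))
            if x.requires_grad:
                # dx = full correlation of g with the kernel flipped along K
                gp = np.pad(g, ((0, 0), (pr, pl), (0, 0)))
                gwin = np.lib.stride_tricks.sliding_window_view(gp, K, axis=1)
                gcols = np.ascontiguousarray(gwin.transpose(0, 1, 3, 2)).reshape(
                    N * L, K * Cout
                )
                wflip = w.data[::-1].transpose(0, 2, 1).reshape(K * Cout, Cin)
                x._accum((gcols @ wflip).reshape(N, L, Cin))

        out._backward = backward
    return out
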