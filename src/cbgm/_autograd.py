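"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the CBGM network needs: broadcasting
arithmetic, matmul, pointwise nonlinearities, reductions, slicing/stacking,
1-D convolution, max pooling and a fused softmax cross-entropy.  Gradients
are retained on every node of the graph, which is what Grad-CAM needs to
read gradients at intermediate convolutional activations.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "Parameter", "stack", "concat", "cross_entropy", "batchnorm",
    "no_grad",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False

#: Compute dtype for the network (float32: 2x memory bandwidth, ample
#: precision for SGD training; the signal-processing code is independent
#: of this and stays float64).
DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_bw", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        if not _GRAD_ENABLED:
            _prev = ()
            requires_grad = False
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._bw = None
        self._prev = _prev

    @property
    def _backward(self):
        return self._bw

    @_backward.setter
    def _backward(self, fn):
        # closures are dropped eagerly in no-grad mode so their captured
        # arrays can be freed
        self._bw = fn if _GRAD_ENABLED else None

    # ---- basic protocol -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    # ---- arithmetic -----------------------------------------------------
    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        out._backward = bw
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out = Tensor(np.matmul(self.data, other.data), _prev=(self, other))

        def bw(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            self._accum(_unbroadcast(ga, self.data.shape))
            other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = bw
        return out

    __matmul__ = matmul

    # ---- pointwise ------------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - out.data**2))
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), _prev=(self,))
        out._backward = lambda g: self._accum(g * out.data * (1.0 - out.data))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    # ---- reductions / shape ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), _prev=(self,))
        inv = np.argsort(axes)
        out._backward = lambda g: self._accum(g.transpose(*inv))
        return out

    def __getitem__(self, idx):
        # basic (slice/int) indexing only: backward scatters without
        # duplicate-index accumulation
        out = Tensor(self.data[idx], _prev=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            full[idx] += g
            self._accum(full)

        out._backward = bw
        return out

    def unbind(self, axis: int = 1) -> list:
        """Split into a list of tensors along `axis` (single stacked backward)."""
        n = self.data.shape[axis]
        parts = [Tensor(np.take(self.data, t, axis=axis), _prev=(self,)) for t in range(n)]

        def make_bw(t):
            def bw(g):
                if self.grad is None:
                    self.grad = np.zeros_like(self.data)
                np.swapaxes(self.grad, 0, axis)[t] += g

            return bw

        for t, p in enumerate(parts):
            p._backward = make_bw(t)
        return parts

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # ---- structured ops --------------------------------------------------
    def conv1d(self, weight: "Tensor", bias: "Tensor") -> "Tensor":
        """'Same'-padded 1-D convolution (cross-correlation).

        self: (B, T, C_in); weight: (K, C_in, C_out); bias: (C_out).
        """
        B, T, C = self.data.shape
        K, _, F = weight.data.shape
        pl, pr = (K - 1) // 2, K // 2
        xp = np.pad(self.data, ((0, 0), (pl, pr), (0, 0)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)  # (B,T,C,K)
        cols = cols.transpose(0, 1, 3, 2).reshape(B, T, K * C)
        wmat = weight.data.reshape(K * C, F)
        out = Tensor(cols @ wmat + bias.data, _prev=(self, weight, bias))

        def bw(g):  # g: (B, T, F)
            bias._accum(g.sum(axis=(0, 1)))
            gw = np.tensordot(cols, g, axes=([0, 1], [0, 1]))  # (K*C, F)
            weight._accum(gw.reshape(K, C, F))
            gcols = (g @ wmat.T).reshape(B, T, K, C)
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[:, k : k + T, :] += gcols[:, :, k, :]
            self._accum(gxp[:, pl : pl + T, :])

        out._backward = bw
        return out

    def max_pool1d(self, pool: int) -> "Tensor":
        """Non-overlapping max pooling along axis 1; trailing remainder dropped."""
        B, T, C = self.data.shape
        To = T // pool
        x = self.data[:, : To * pool, :].reshape(B, To, pool, C)
        arg = x.argmax(axis=2)  # (B, To, C)
        out = Tensor(x.max(axis=2), _prev=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            b, t, c = np.meshgrid(
                np.arange(B), np.arange(To), np.arange(C), indexing="ij"
            )
            full[b, t * pool + arg, c] = g
            self._accum(full)

        out._backward = bw
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # ---- autodiff driver -------------------------------------------------
    def backward(self, retain_all: bool = False):
        """Reverse-mode sweep from a scalar.

        With ``retain_all`` every node keeps its gradient (needed when
        gradients at intermediate activations are read, e.g. Grad-CAM);
        otherwise non-leaf gradients are freed as soon as they have been
        propagated, halving peak memory.
        """
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
                if not retain_all and t._prev:
                    t.grad = None


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def stack(tensors: list, axis: int = 1) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _prev=tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))

    out._backward = bw
    return out


def concat(tensors: list, axis: int = -1) -> Tensor:
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors)
    )
    sizes = [t.data.shape[axis] for t in tensors]

    def bw(g):
        parts = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        for t, p in zip(tensors, parts):
            t._accum(p)

    out._backward = bw
    return out


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Fused batch normalization over axes (0, 1) of a (B, T, C) tensor."""
    axes = (0, 1)
    n = x.data.shape[0] * x.data.shape[1]
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(gamma.data * xhat + beta.data, _prev=(x, gamma, beta))

    def bw(g):
        beta._accum(g.sum(axis=axes))
        gamma._accum((g * xhat).sum(axis=axes))
        dxhat = g * gamma.data
        s1 = dxhat.sum(axis=axes, keepdims=True)
        s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
        x._accum(inv / n * (n * dxhat - s1 - xhat * s2))

    out._backward = bw
    return out


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer `targets` under softmax(logits)."""
    z = logits.data.astype(np.float64)
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    n = z.shape[0]
    nll = (lse.ravel() - z[np.arange(n), targets]).mean()
    out = Tensor(nll, _prev=(logits,))

    def bw(g):
        p = np.exp(z - lse)
        p[np.arange(n), targets] -= 1.0
        logits._accum(g * p / n)

    out._backward = bw
    return out
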