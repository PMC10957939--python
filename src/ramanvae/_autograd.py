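"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the spectral autoencoder and classifier
need: broadcasting arithmetic, matmul, reductions, elementwise
nonlinearities, strided 1-D convolution (via im2col), zero-insertion
upsampling for transposed convolution, slicing/concatenation, atan2 for
phase losses, and a fused softmax cross-entropy.  Everything is float64
and single-threaded numpy, so runs are bit-reproducible given a seed.

The design follows the familiar tape pattern: each `Tensor` records its
parents and a closure that scatters the incoming cotangent to them;
`backward()` walks the graph in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # keep numpy from treating Tensors as object arrays in `ndarray * Tensor`
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw():
            self._accum(_unbroadcast(out.grad, self.shape))
            other._accum(_unbroadcast(out.grad, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda: self._accum(-out.grad)
        return out

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw():
            self._accum(_unbroadcast(out.grad * other.data, self.shape))
            other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw():
            self._accum(_unbroadcast(out.grad / other.data, self.shape))
            other._accum(_unbroadcast(-out.grad * self.data / other.data**2, other.shape))

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _parents=(self,))
        out._backward = lambda: self._accum(out.grad * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw():
            a, b, g = self.data, other.data, out.grad
            if a.ndim == 2 and b.ndim == 2:
                self._accum(g @ b.T)
                other._accum(a.T @ g)
            elif a.ndim == 1 and b.ndim == 2:
                self._accum(g @ b.T)
                other._accum(np.outer(a, g))
            else:
                raise NotImplementedError("matmul grads support 2-D operands")

        out._backward = bw
        return out

    # -- elementwise ------------------------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))
        out._backward = lambda: self._accum(out.grad * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda: self._accum(out.grad / self.data)
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), _parents=(self,))
        out._backward = lambda: self._accum(out.grad * 0.5 / np.maximum(out.data, 1e-300))
        return out

    def sin(self):
        out = Tensor(np.sin(self.data), _parents=(self,))
        out._backward = lambda: self._accum(out.grad * np.cos(self.data))
        return out

    def cos(self):
        out = Tensor(np.cos(self.data), _parents=(self,))
        out._backward = lambda: self._accum(-out.grad * np.sin(self.data))
        return out

    def leaky_relu(self, slope: float = 0.01):
        mask = np.where(self.data > 0, 1.0, slope)
        out = Tensor(self.data * mask, _parents=(self,))
        out._backward = lambda: self._accum(out.grad * mask)
        return out

    def clip(self, lo: float, hi: float):
        """Clamp with straight-through gradient inside the bounds."""
        mask = ((self.data >= lo) & (self.data <= hi)).astype(np.float64)
        out = Tensor(np.clip(self.data, lo, hi), _parents=(self,))
        out._backward = lambda: self._accum(out.grad * mask)
        return out

    # -- reductions / shaping --------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda: self._accum(out.grad.reshape(self.shape))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bw():
            g = np.zeros_like(self.data)
            g[idx] = out.grad
            self._accum(g)

        out._backward = bw
        return out


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))

    def bw():
        splits = np.cumsum([t.data.shape[axis] for t in tensors])[:-1]
        for t, g in zip(tensors, np.split(out.grad, splits, axis=axis)):
            t._accum(g)

    out._backward = bw
    return out


def atan2(y: Tensor, x: Tensor) -> Tensor:
    y, x = Tensor.as_tensor(y), Tensor.as_tensor(x)
    out = Tensor(np.arctan2(y.data, x.data), _parents=(y, x))

    def bw():
        denom = y.data**2 + x.data**2 + 1e-300
        y._accum(_unbroadcast(out.grad * x.data / denom, y.shape))
        x._accum(_unbroadcast(-out.grad * y.data / denom, x.shape))

    out._backward = bw
    return out


# -- convolution primitives ----------------------------------------------


def _im2col(x: np.ndarray, K: int, stride: int, pad: int):
    """(B, C, L) -> (B, Lout, C*K) patch matrix (and the padded input shape)."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad))) if pad else x
    B, C, L = xp.shape
    Lout = (L - K) // stride + 1
    s0, s1, s2 = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, shape=(B, C, Lout, K), strides=(s0, s1, s2 * stride, s2), writeable=False
    )
    cols = win.transpose(0, 2, 1, 3).reshape(B, Lout, C * K)
    return cols, xp.shape, Lout


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """1-D convolution: x (B, Cin, L), w (Cout, Cin, K), b (Cout,)."""
    B, Cin, L = x.shape
    Cout, _, K = w.shape
    cols, pshape, Lout = _im2col(x.data, K, stride, pad)
    wmat = w.data.reshape(Cout, Cin * K)
    y = cols @ wmat.T + b.data  # (B, Lout, Cout)
    out = Tensor(np.ascontiguousarray(y.transpose(0, 2, 1)), _parents=(x, w, b))

    def bw():
        g = out.grad.transpose(0, 2, 1)  # (B, Lout, Cout)
        b._accum(g.sum(axis=(0, 1)))
        gw = g.reshape(-1, Cout).T @ cols.reshape(-1, Cin * K)
        w._accum(gw.reshape(Cout, Cin, K))
        gcols = g @ wmat  # (B, Lout, Cin*K)
        gcols = gcols.reshape(B, Lout, Cin, K).transpose(0, 2, 1, 3)
        gxp = np.zeros(pshape)
        for k in range(K):
            gxp[:, :, k : k + Lout * stride : stride] += gcols[:, :, :, k]
        x._accum(gxp[:, :, pad : pshape[2] - pad] if pad else gxp)

    out._backward = bw
    return out


def upsample_zeros(x: Tensor, factor: int) -> Tensor:
    """Insert `factor - 1` zeros between samples along the last axis."""
    B, C, L = x.shape
    y = np.zeros((B, C, L * factor))
    y[:, :, ::factor] = x.data
    out = Tensor(y, _parents=(x,))
    out._backward = lambda: x._accum(out.grad[:, :, ::factor])
    return out


# -- fused classification loss -------------------------------------------


def softmax_cross_entropy(logits: Tensor, onehot: np.ndarray, sample_weights: np.ndarray | None = None) -> Tensor:
    """Weighted mean cross-entropy with a numerically stable fused softmax."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    w = np.ones(n) if sample_weights is None else np.asarray(sample_weights, dtype=np.float64)
    wsum = w.sum()
    nll = -(onehot * np.log(np.maximum(p, 1e-300))).sum(axis=1)
    out = Tensor((w * nll).sum() / wsum, _parents=(logits,))

    def bw():
        g = (p - onehot) * (w / wsum)[:, None]
        logits._accum(out.grad * g)

    out._backward = bw
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


# -- optimizer ------------------------------------------------------------


class Adam:
    """Adaptive-moment first-order optimizer over a list of Tensors."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
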