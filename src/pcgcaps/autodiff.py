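"""Minimal reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: :class:`Tensor` wraps an ndarray,
records the operations applied to it, and :meth:`Tensor.backward` walks the
tape in reverse topological order accumulating gradients.  Only the
primitives the capsule network needs are provided (broadcast arithmetic,
matmul/einsum contractions, valid-padding strided convolution, elementwise
nonlinearities and axis reductions), each with an analytically derived
adjoint.  Gradient correctness is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "softmax", "relu", "sigmoid", "conv2d", "einsum"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def build(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                build(p)
            topo.append(t)

        build(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic ----------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        return self * self._wrap(other) ** (-1.0)

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** (-1.0)

    def __pow__(self, n: float):
        out = Tensor(self.data**n, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * n * self.data ** (n - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        out._backward = bw
        return out

    # -- elementwise ---------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out.data)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = bw
        return out

    def sqrt(self):
        return self**0.5

    # -- reductions / reshaping ----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))

        out._backward = bw
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        out._backward = bw
        return out

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


# -- nonlinearities ----------------------------------------------------
def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), _prev=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * (x.data > 0))

    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    out = Tensor(1.0 / (1.0 + np.exp(-x.data)), _prev=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * out.data * (1.0 - out.data))

    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # shift by the (constant) max for stability; softmax is shift invariant
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


# -- contractions ------------------------------------------------------
def einsum(spec: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum with autodiff.

    Requires every index of each operand to appear in the output or the
    other operand (no internal diagonals), which holds for ordinary
    tensor contractions.
    """
    lhs, out_sub = spec.split("->")
    sa, sb = lhs.split(",")
    out = Tensor(np.einsum(spec, a.data, b.data), _prev=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accum(np.einsum(f"{out_sub},{sb}->{sa}", g, b.data))
        if b.requires_grad:
            b._accum(np.einsum(f"{out_sub},{sa}->{sb}", g, a.data))

    out._backward = bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int) -> Tensor:
    """Valid-padding strided 2-D cross-correlation.

    `x` is NHWC, `w` is (K, K, C, F).  Output spatial dims are
    floor((H-K)/S)+1 by floor((W-K)/S)+1 — no padding, floor division.
    """
    K = w.shape[0]
    s = stride
    N, H, W, C = x.shape
    if K > H or K > W:
        raise ValueError(f"kernel {K} larger than input {H}x{W}")
    Ho = (H - K) // s + 1
    Wo = (W - K) // s + 1
    F = w.shape[3]
    # (N, H-K+1, W-K+1, C, K, K) windows, then stride subsample
    win = np.lib.stride_tricks.sliding_window_view(x.data, (K, K), axis=(1, 2))
    win = win[:, :: s, :: s][:, :Ho, :Wo]  # (N, Ho, Wo, C, K, K)
    patches = win.transpose(0, 1, 2, 4, 5, 3).reshape(N, Ho, Wo, K * K * C)
    wmat = w.data.reshape(K * K * C, F)
    out_data = patches @ wmat
    if b is not None:
        out_data = out_data + b.data
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _prev=prev)

    def bw(g):
        if w.requires_grad:
            gw = np.einsum("nhwp,nhwf->pf", patches, g)
            w._accum(gw.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            gcol = (g @ wmat.T).reshape(N, Ho, Wo, K, K, C)
            gx = np.zeros_like(x.data)
            for u in range(K):
                for v in range(K):
                    gx[:, u : u + s * Ho : s, v : v + s * Wo : s, :] += gcol[
                        :, :, :, u, v, :
                    ]
            x._accum(gx)

    out._backward = bw
    return out


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
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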