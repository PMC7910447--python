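"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the accuracy network needs: broadcasted
arithmetic, matmul, reshape/transpose, ELU/sigmoid/softmax/log/exp,
axis reductions, concatenation, and 2D/3D convolutions (dilated 3x3 and
3x3x3 kernels with "same" padding) plus 3D average pooling.  Convolutions
are implemented as shifted-slice matmuls, which keeps both passes pure
numpy.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes introduced or broadcast relative to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.shape)
        return Tensor(self.data + other.data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.shape)
        return Tensor(self.data * other.data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / other.data, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(-g * self.data / other.data ** 2,
                                           other.shape)
        return Tensor(self.data / other.data, parents=(self, other), backward=bw)

    def __pow__(self, exp: float):
        def bw(g):
            if self.requires_grad:
                self.grad += g * exp * self.data ** (exp - 1)
        return Tensor(self.data ** exp, parents=(self,), backward=bw)

    def matmul(self, other):
        other = self._wrap(other)
        out = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                          self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                           other.shape)
        return Tensor(out, parents=(self, other), backward=bw)

    __matmul__ = matmul

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        old = self.shape

        def bw(g):
            if self.requires_grad:
                self.grad += g.reshape(old)
        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bw)

    def transpose(self, axes: tuple):
        inv = tuple(np.argsort(axes))

        def bw(g):
            if self.requires_grad:
                self.grad += g.transpose(inv)
        return Tensor(self.data.transpose(axes), parents=(self,), backward=bw)

    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += np.full_like(self.data, float(g))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gg, self.shape)
        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        elif isinstance(axis, tuple):
            count = int(np.prod([self.data.shape[a] for a in axis]))
        else:
            count = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- nonlinearities ----------------------------------------------------

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        out = np.where(pos, self.data, alpha * (np.exp(np.minimum(self.data, 0)) - 1))

        def bw(g):
            if self.requires_grad:
                self.grad += g * np.where(pos, 1.0, out + alpha)
        return Tensor(out, parents=(self,), backward=bw)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))

        def bw(g):
            if self.requires_grad:
                self.grad += g * out * (1.0 - out)
        return Tensor(out, parents=(self,), backward=bw)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            if self.requires_grad:
                dot = (g * p).sum(axis=axis, keepdims=True)
                self.grad += p * (g - dot)
        return Tensor(p, parents=(self,), backward=bw)

    def log(self, eps: float = 1e-12):
        def bw(g):
            if self.requires_grad:
                self.grad += g / (self.data + eps)
        return Tensor(np.log(self.data + eps), parents=(self,), backward=bw)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.grad += g[tuple(sl)]
    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=bw)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, dilation: int = 1) -> Tensor:
    """Same-padded 3x3 2D convolution over an (H, W, Cin) tensor."""
    h, w, cin = x.shape
    kh, kw, _, cout = weight.shape
    pad = dilation * (kh // 2)
    xp = np.pad(x.data, ((pad, pad), (pad, pad), (0, 0)))
    out = np.zeros((h, w, cout))
    for a in range(kh):
        for b in range(kw):
            patch = xp[a * dilation:a * dilation + h, b * dilation:b * dilation + w]
            out += patch @ weight.data[a, b]
    out += bias.data

    def bw(g):
        if weight.requires_grad or x.requires_grad:
            gxp = np.zeros_like(xp)
            gflat = g.reshape(-1, cout)
            for a in range(kh):
                for b in range(kw):
                    patch = xp[a * dilation:a * dilation + h,
                               b * dilation:b * dilation + w]
                    if weight.requires_grad:
                        weight.grad[a, b] += patch.reshape(-1, cin).T @ gflat
                    if x.requires_grad:
                        gxp[a * dilation:a * dilation + h,
                            b * dilation:b * dilation + w] += g @ weight.data[a, b].T
            if x.requires_grad:
                x.grad += gxp[pad:pad + h, pad:pad + w]
        if bias.requires_grad:
            bias.grad += g.sum(axis=(0, 1))
    return Tensor(out, parents=(x, weight, bias), backward=bw)


def conv3d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-padded 3x3x3 3D convolution over a (B, G, G, G, Cin) batch."""
    bsz, g1, g2, g3, cin = x.shape
    k = weight.shape[0]
    cout = weight.shape[-1]
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (pad, pad), (0, 0)))
    out = np.zeros((bsz, g1, g2, g3, cout))
    for a in range(k):
        for b in range(k):
            for c in range(k):
                patch = xp[:, a:a + g1, b:b + g2, c:c + g3]
                out += patch @ weight.data[a, b, c]
    out += bias.data

    def bw(g):
        gxp = np.zeros_like(xp) if x.requires_grad else None
        gflat = g.reshape(-1, cout)
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    patch = xp[:, a:a + g1, b:b + g2, c:c + g3]
                    if weight.requires_grad:
                        weight.grad[a, b, c] += patch.reshape(-1, cin).T @ gflat
                    if x.requires_grad:
                        gxp[:, a:a + g1, b:b + g2, c:c + g3] += g @ weight.data[a, b, c].T
        if x.requires_grad:
            x.grad += gxp[:, pad:pad + g1, pad:pad + g2, pad:pad + g3]
        if bias.requires_grad:
            bias.grad += g.sum(axis=(0, 1, 2, 3))
    return Tensor(out, parents=(x, weight, bias), backward=bw)


def avgpool3d(x: Tensor, factor: int = 2) -> Tensor:
    """Non-overlapping average pooling of a (B, G, G, G, C) tensor."""
    bsz, g1, g2, g3, ch = x.shape
    if any(s % factor for s in (g1, g2, g3)):
        raise ValueError("grid size must be divisible by the pooling factor")
    h1, h2, h3 = g1 // factor, g2 // factor, g3 // factor
    r = x.data.reshape(bsz, h1, factor, h2, factor, h3, factor, ch)
    out = r.mean(axis=(2, 4, 6))
    scale = 1.0 / factor ** 3

    def bw(g):
        if x.requires_grad:
            gg = g[:, :, None, :, None, :, None, :] * scale
            self_grad = np.broadcast_to(
                gg, (bsz, h1, factor, h2, factor, h3, factor, ch))
            x.grad += self_grad.reshape(x.shape)
    return Tensor(out, parents=(x,), backward=bw)


class Adam:
    """ADAM optimizer over a flat dict of parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 5e-4,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g ** 2
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
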