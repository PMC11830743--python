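"""Minimal reverse-mode automatic differentiation and neural-net layers.

A deliberately small engine — just the operations the booster VAE needs —
built on numpy arrays.  Convolutions are lowered to one GEMM per kernel
tap; gradients are accumulated by walking the tape in reverse topological
order.  Exactness of every operation's vector-Jacobian product is enforced
by finite-difference tests in the suite.
"""

from __future__ import annotations

import numpy as np


__all__ = [
    "Tensor", "Module", "Linear", "Conv2d", "ResBlock", "UpsampleBlock",
    "Adam", "relu", "sigmoid", "softplus", "exp", "concat", "conv2d",
    "upsample2x", "mean_all", "sum_all",
]


class Tensor:
    """A numpy array plus the tape machinery for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "_parents", "_bwd")

    def __init__(self, data, _parents=(), _bwd=None):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=float)
        self.grad = None
        self._parents = _parents
        self._bwd = _bwd

    # -- introspection ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype})"

    # -- graph --------------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._bwd is not None:
                t._bwd(t.grad)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = _wrap(other, self.data.dtype)
        out = Tensor(self.data + other.data, (self, other))

        def bwd(g):
            _acc(self, _unbroadcast(g, self.data.shape))
            _acc(other, _unbroadcast(g, other.data.shape))

        out._bwd = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._bwd = lambda g: _acc(self, -g)
        return out

    def __sub__(self, other):
        return self + (-_wrap(other, self.data.dtype))

    def __rsub__(self, other):
        return _wrap(other, self.data.dtype) + (-self)

    def __mul__(self, other):
        other = _wrap(other, self.data.dtype)
        out = Tensor(self.data * other.data, (self, other))

        def bwd(g):
            _acc(self, _unbroadcast(g * other.data, self.data.shape))
            _acc(other, _unbroadcast(g * self.data, other.data.shape))

        out._bwd = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("divide by a Tensor is unsupported; multiply by its inverse")
        return self * (1.0 / other)

    def __pow__(self, p):
        assert isinstance(p, (int, float))
        out = Tensor(self.data**p, (self,))
        out._bwd = lambda g: _acc(self, g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        assert isinstance(other, Tensor) and other.data.ndim == 2
        out = Tensor(self.data @ other.data, (self, other))

        def bwd(g):
            _acc(self, g @ other.data.T)
            a = self.data.reshape(-1, self.data.shape[-1])
            _acc(other, a.T @ g.reshape(-1, g.shape[-1]))

        out._bwd = bwd
        return out

    # -- shape --------------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._bwd = lambda g: _acc(self, g.reshape(self.data.shape))
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            _acc(self, np.broadcast_to(g, self.data.shape).copy())

        out._bwd = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def _wrap(x, dtype):
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _acc(t, g):
    if t.grad is None:
        t.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
    else:
        t.grad = t.grad + g


def _unbroadcast(g, shape):
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g.reshape(shape)


# -- elementwise nonlinearities -------------------------------------------


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), (x,))
    out._bwd = lambda g: _acc(x, g * (x.data > 0))
    return out


def sigmoid(x: Tensor) -> Tensor:
    from scipy.special import expit

    s = expit(x.data)
    out = Tensor(s, (x,))
    out._bwd = lambda g: _acc(x, g * s * (1.0 - s))
    return out


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), numerically stable."""
    from scipy.special import expit

    out = Tensor(np.logaddexp(0.0, x.data), (x,))
    out._bwd = lambda g: _acc(x, g * expit(x.data))
    return out


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)
    out = Tensor(e, (x,))
    out._bwd = lambda g: _acc(x, g * e)
    return out


def concat(tensors, axis=1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(lo), int(hi))
            _acc(t, g[tuple(sl)])

    out._bwd = bwd
    return out


def sum_all(x: Tensor) -> Tensor:
    return x.sum()


def mean_all(x: Tensor) -> Tensor:
    return x.mean()


# -- convolution -----------------------------------------------------------


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout.

    Lowered to one GEMM per kernel tap (shift-and-accumulate), which beats
    im2col at the small channel counts used here by avoiding the large
    column-matrix copies.
    """
    cout, cin, kh, kw = w.data.shape
    n = x.data.shape[0]
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    )
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    acc = np.zeros((cout, n, ho, wo), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
            acc += np.tensordot(w.data[:, :, i, j], xs, axes=([1], [1]))
    out_data = acc.transpose(1, 0, 2, 3) + b.data[None, :, None, None]
    out = Tensor(out_data, (x, w, b))

    def bwd(g):
        db = g.sum(axis=(0, 2, 3))
        dw = np.empty_like(w.data)
        dxp = np.zeros((cin, n, hp, wp), dtype=g.dtype)
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
                dw[:, :, i, j] = np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
                dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                    np.tensordot(w.data[:, :, i, j], g, axes=([0], [1]))
                )
        dx = dxp.transpose(1, 0, 2, 3)
        if pad:
            dx = dx[:, :, pad:-pad, pad:-pad]
        _acc(x, np.ascontiguousarray(dx))
        _acc(w, dw)
        _acc(b, db)

    out._bwd = bwd
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbor 2x spatial upsampling, NCHW."""
    d = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    out = Tensor(d, (x,))

    def bwd(g):
        n, c, h, w = g.shape
        _acc(x, g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)))

    out._bwd = bwd
    return out


# -- modules ---------------------------------------------------------------


class Module:
    """Parameter container with recursive traversal."""

    def __init__(self):
        self._params: list[Tensor] = []
        self._mods: list[Module] = []

    def _param(self, array) -> Tensor:
        p = Tensor(array)
        self._params.append(p)
        return p

    def _mod(self, module: "Module") -> "Module":
        self._mods.append(module)
        return module

    def parameters(self):
        yield from self._params
        for m in self._mods:
            yield from m.parameters()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = list(self.parameters())
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state array shape mismatch")
            p.data = a.astype(p.data.dtype)


class Linear(Module):
    def __init__(self, nin, nout, rng, dtype=np.float32, gain=2.0):
        super().__init__()
        std = np.sqrt(gain / nin)
        self.w = self._param(rng.normal(0.0, std, (nin, nout)).astype(dtype))
        self.b = self._param(np.zeros(nout, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    def __init__(self, cin, cout, k, rng, stride=1, pad=None, dtype=np.float32, gain=2.0):
        super().__init__()
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        std = np.sqrt(gain / (cin * k * k))
        self.w = self._param(rng.normal(0.0, std, (cout, cin, k, k)).astype(dtype))
        self.b = self._param(np.zeros(cout, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class ResBlock(Module):
    """conv-relu-conv with a (projected) skip connection; optional stride-2."""

    def __init__(self, cin, cout, rng, stride=1, dtype=np.float32):
        super().__init__()
        self.conv1 = self._mod(Conv2d(cin, cout, 3, rng, stride=stride, dtype=dtype))
        self.conv2 = self._mod(Conv2d(cout, cout, 3, rng, dtype=dtype))
        self.skip = None
        if stride != 1 or cin != cout:
            self.skip = self._mod(Conv2d(cin, cout, 1, rng, stride=stride, pad=0, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv2(relu(self.conv1(x)))
        s = x if self.skip is None else self.skip(x)
        return relu(h + s)


class UpsampleBlock(Module):
    """nearest-2x upsample followed by a residual block."""

    def __init__(self, cin, cout, rng, dtype=np.float32):
        super().__init__()
        self.block = self._mod(ResBlock(cin, cout, rng, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return self.block(upsample2x(x))


class Adam:
    """Adam optimizer on a fixed parameter list."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data = p.data - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
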