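"""A compact reverse-mode automatic-differentiation engine on numpy.

This module provides exactly the tensor operations the conditional VAE
needs — dense layers, 3x3 convolutions, batch normalisation, 2x2 max
pooling, nearest-neighbour upsampling, the usual pointwise nonlinearities,
and reductions — together with parameter modules and an Adam optimiser.
Everything runs in float64 on the CPU; gradients are validated against
central finite differences in the test suite.

Graphs are built eagerly: each operation returns a :class:`Tensor` holding
its value, its parents, and a closure that routes the upstream gradient to
them.  ``Tensor.backward()`` runs the closures in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "Conv2d",
    "BatchNorm1d",
    "BatchNorm2d",
    "Dropout",
    "Adam",
    "concat",
    "conv2d",
    "gauss_blur_valid",
    "maxpool2d",
    "avgpool2d",
    "upsample_nearest2",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient back down to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad = None
        self._parents = parents if requires_grad else ()
        self._backward = backward if requires_grad else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out_req = self.requires_grad or other.requires_grad

        def bw(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return Tensor(self.data + other.data, out_req, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor(-self.data, self.requires_grad, (self,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_req = self.requires_grad or other.requires_grad

        def bw(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return Tensor(self.data * other.data, out_req, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self.pow(-1.0)

    def pow(self, p: float) -> "Tensor":
        out = self.data**p

        def bw(g):
            self._accum(g * p * self.data ** (p - 1.0))

        return Tensor(out, self.requires_grad, (self,), bw)

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out_req = self.requires_grad or other.requires_grad

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor(self.data @ other.data, out_req, (self, other), bw)

    __matmul__ = matmul

    # -------------------------------------------------------------- pointwise
    def exp(self) -> "Tensor":
        out = np.exp(self.data)

        def bw(g):
            self._accum(g * out)

        return Tensor(out, self.requires_grad, (self,), bw)

    def log(self) -> "Tensor":
        def bw(g):
            self._accum(g / self.data)

        return Tensor(np.log(self.data), self.requires_grad, (self,), bw)

    def sigmoid(self) -> "Tensor":
        out = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * out * (1.0 - out))

        return Tensor(out, self.requires_grad, (self,), bw)

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        mask = self.data > 0

        def bw(g):
            self._accum(g * np.where(mask, 1.0, slope))

        return Tensor(np.where(mask, self.data, slope * self.data), self.requires_grad, (self,), bw)

    def clamp_min(self, lo: float) -> "Tensor":
        """Lower clamp; the gradient passes only where the input exceeds ``lo``."""
        mask = self.data > lo

        def bw(g):
            self._accum(g * mask)

        return Tensor(np.maximum(self.data, lo), self.requires_grad, (self,), bw)

    def clamp(self, lo: float, hi: float) -> "Tensor":
        """Two-sided clamp; the gradient passes only strictly inside the range."""
        mask = (self.data > lo) & (self.data < hi)

        def bw(g):
            self._accum(g * mask)

        return Tensor(np.clip(self.data, lo, hi), self.requires_grad, (self,), bw)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                ax = (axis,) if isinstance(axis, int) else tuple(axis)
                ax = tuple(a % self.data.ndim for a in ax)
                shape = [1 if i in ax else s for i, s in enumerate(self.data.shape)]
                g = g.reshape(shape)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor(out, self.requires_grad, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            ax = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bw(g):
            self._accum(g.reshape(old))

        return Tensor(self.data.reshape(shape), self.requires_grad, (self,), bw)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    return Tensor(out, req, tuple(tensors), bw)


# ------------------------------------------------------------------ spatial ops

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int = 1) -> Tensor:
    """2-D convolution, stride 1, NCHW layout, zero padding ``pad``."""
    n, c, h, wd = x.data.shape
    o, c2, kh, kw = w.data.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, kernel {c2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho, wo = h + 2 * pad - kh + 1, wd + 2 * pad - kw + 1
    out = np.zeros((n, o, ho, wo))
    for di in range(kh):
        for dj in range(kw):
            out += np.einsum(
                "oc,nchw->nohw",
                w.data[:, :, di, dj],
                xp[:, :, di : di + ho, dj : dj + wo],
                optimize=True,
            )
    if b is not None:
        out += b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    req = any(t.requires_grad for t in parents)

    def bw(g):
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for di in range(kh):
                for dj in range(kw):
                    dw[:, :, di, dj] = np.einsum(
                        "nohw,nchw->oc", g, xp[:, :, di : di + ho, dj : dj + wo],
                        optimize=True,
                    )
            w._accum(dw)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for di in range(kh):
                for dj in range(kw):
                    dxp[:, :, di : di + ho, dj : dj + wo] += np.einsum(
                        "oc,nohw->nchw", w.data[:, :, di, dj], g, optimize=True
                    )
            x._accum(dxp[:, :, pad : pad + h, pad : pad + wd] if pad else dxp)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    return Tensor(out, req, parents, bw)


def maxpool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; ties resolve to the first occurrence."""
    n, c, h, w = x.data.shape
    ho, wo = h // 2, w // 2
    xr = (
        x.data[:, :, : ho * 2, : wo * 2]
        .reshape(n, c, ho, 2, wo, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, ho, wo, 4)
    )
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        gz = np.zeros((n, c, ho, wo, 4))
        np.put_along_axis(gz, idx[..., None], g[..., None], axis=-1)
        gx = np.zeros_like(x.data)
        gx[:, :, : ho * 2, : wo * 2] = (
            gz.reshape(n, c, ho, wo, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, ho * 2, wo * 2)
        )
        x._accum(gx)

    return Tensor(out, x.requires_grad, (x,), bw)


def avgpool2d(x: Tensor) -> Tensor:
    """2x2 average pooling, stride 2 (used for multiscale image pyramids)."""
    n, c, h, w = x.data.shape
    ho, wo = h // 2, w // 2
    out = x.data[:, :, : ho * 2, : wo * 2].reshape(n, c, ho, 2, wo, 2).mean(axis=(3, 5))

    def bw(g):
        gx = np.zeros_like(x.data)
        gx[:, :, : ho * 2, : wo * 2] = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0
        x._accum(gx)

    return Tensor(out, x.requires_grad, (x,), bw)


def gauss_blur_valid(x: Tensor, kernel_1d: np.ndarray) -> Tensor:
    """Separable symmetric blur with 'valid' output, NCHW layout.

    Implemented with C-level 1-D correlations rather than the generic
    convolution loop — the multiscale similarity loss calls this many times
    per training step.  The kernel must be odd-length and symmetric.
    """
    from scipy import ndimage as _ndi

    k = np.asarray(kernel_1d, dtype=np.float64)
    m = len(k) // 2

    def corr_valid(a: np.ndarray, axis: int) -> np.ndarray:
        out = _ndi.correlate1d(a, k, axis=axis, mode="constant")
        sl = [slice(None)] * a.ndim
        sl[axis] = slice(m, a.shape[axis] - m)
        return out[tuple(sl)]

    out = corr_valid(corr_valid(x.data, 2), 3)

    def bw(g):
        # gradient of a valid correlation is a full convolution; the
        # symmetric kernel makes convolution == correlation
        pad = [(0, 0), (0, 0), (2 * m, 2 * m), (0, 0)]
        gp = corr_valid(np.pad(g, pad), 2)
        pad = [(0, 0), (0, 0), (0, 0), (2 * m, 2 * m)]
        x._accum(corr_valid(np.pad(gp, pad), 3))

    return Tensor(out, x.requires_grad, (x,), bw)


def upsample_nearest2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x unpooling: each pixel fills its 2x2 block."""
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    n, c, h, w = x.data.shape

    def bw(g):
        x._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor(out, x.requires_grad, (x,), bw)


# ---------------------------------------------------------------------- modules

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal parameter container with train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Parameter):
                        params.append(item)
                    elif isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def state_arrays(self) -> list[np.ndarray]:
        """Copies of all parameter arrays, in ``parameters()`` order."""
        return [p.data.copy() for p in self.parameters()]

    def load_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = a.copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / n_in)
        self.weight = Parameter(rng.normal(0.0, std, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3, pad: int = 1):
        super().__init__()
        std = np.sqrt(2.0 / (c_in * k * k))
        self.weight = Parameter(rng.normal(0.0, std, size=(c_out, c_in, k, k)))
        self.bias = Parameter(np.zeros(c_out))
        self.pad = pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, pad=self.pad)


class _BatchNorm(Module):
    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(n))
        self.beta = Parameter(np.zeros(n))
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps

    def _normalise(self, x: Tensor, axes: tuple, shape: tuple) -> Tensor:
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            # update running statistics outside the graph
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
            xhat = xc * (var + self.eps).pow(-0.5)
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
            xhat = (x - mu) * (var + self.eps).pow(-0.5)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class BatchNorm2d(_BatchNorm):
    def __call__(self, x: Tensor) -> Tensor:
        return self._normalise(x, axes=(0, 2, 3), shape=(1, -1, 1, 1))


class BatchNorm1d(_BatchNorm):
    def __call__(self, x: Tensor) -> Tensor:
        return self._normalise(x, axes=(0,), shape=(1, -1))


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        mask = (self.rng.random(x.data.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Adam:
    """Adam optimiser with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

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
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
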