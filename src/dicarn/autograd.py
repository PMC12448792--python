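"""A compact reverse-mode automatic-differentiation engine on numpy arrays.

The network in :mod:`dicarn.model` needs exactly the operations implemented
here: broadcast arithmetic, batched matrix multiplication, ReLU, softmax,
channel concatenation, reshaping and a dilated 2-D convolution primitive.
Keeping the engine in-package makes the whole training loop a pure
numpy computation — deterministic, dependency-light and easy to verify with
finite differences (see the test suite).

Conventions: tensors wrap float64 ``numpy`` arrays; gradients accumulate in
``Tensor.grad`` after ``Tensor.backward()``; the graph is a DAG traversed in
reverse topological order.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    g = grad
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _make(data, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = parents
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other: "Tensor | float") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), bwd)

    def __mul__(self, other: "Tensor | float") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), bwd)

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other: "Tensor | float") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    __radd__ = __add__
    __rmul__ = __mul__

    def square(self) -> "Tensor":
        return self * self

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def matmul(self, other: "Tensor") -> "Tensor":
        """Batched matrix multiplication with numpy ``matmul`` semantics."""

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.data.shape))

        return Tensor._make(np.matmul(self.data, other.data), (self, other), bwd)

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.transpose(*inv))

        return Tensor._make(self.data.transpose(*axes), (self,), bwd)

    def mean(self) -> "Tensor":
        n = self.data.size

        def bwd(g):
            if self.requires_grad:
                self._accumulate(np.full_like(self.data, float(g) / n))

        return Tensor._make(self.data.mean(), (self,), bwd)

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accumulate(s * (g - dot))

        return Tensor._make(s, (self,), bwd)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        parts = np.split(g, splits, axis=axis)
        for t, part in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(part)

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, dilation: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) with dilated taps.

    ``x`` is ``(N, C_in, H, W)``, ``w`` is ``(C_out, C_in, KH, KW)``; tap ``k``
    of the kernel reads input position ``i + dilation * k`` per axis, so the
    receptive footprint grows with ``dilation`` while the parameter count does
    not.  Zero padding of ``padding`` pixels per side; output spatial size is
    ``H + 2 * padding - dilation * (KH - 1)``.
    """
    n, cin, hh, ww = x.data.shape
    cout, cin2, kh, kw = w.data.shape
    if cin != cin2:
        raise ValueError(f"channel mismatch: input {cin}, kernel {cin2}")
    d = dilation
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = xp.shape[2] - d * (kh - 1)
    wo = xp.shape[3] - d * (kw - 1)
    if ho <= 0 or wo <= 0:
        raise ValueError("input smaller than dilated kernel footprint")
    cols = np.empty((n, cin, kh, kw, ho, wo))
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i * d : i * d + ho, j * d : j * d + wo]
    cols2 = cols.reshape(n, cin * kh * kw, ho * wo)
    wmat = w.data.reshape(cout, cin * kh * kw)
    out = np.einsum("of,nfl->nol", wmat, cols2).reshape(n, cout, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, cout, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gmat = g.reshape(n, cout, ho * wo)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.einsum("nol,nfl->of", gmat, cols2)
            w._accumulate(gw.reshape(w.data.shape))
        if x.requires_grad:
            gcols = np.einsum("of,nol->nfl", wmat, gmat).reshape(n, cin, kh, kw, ho, wo)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i * d : i * d + ho, j * d : j * d + wo] += gcols[:, :, i, j]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    return Tensor._make(out, parents, bwd)


# ---------------------------------------------------------------------------
# Parameters and optimization
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """He-style uniform initialization, bound ``sqrt(6 / fan_in)``."""
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

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
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
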