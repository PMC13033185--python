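"""Minimal reverse-mode automatic differentiation over numpy arrays.

All model training in this package (ZINB autoencoder, contrastive query
encoder, teacher/student classifiers) runs on this core: a ``Tensor`` wraps
an ndarray and records enough of the computation graph to backpropagate.
The op set is deliberately small — dense layers, the usual nonlinearities,
and the special functions the ZINB likelihood needs (``lgamma`` with a
digamma gradient).

Gradients are checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import special


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, grad):
        grad = _unbroadcast(grad, self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _wrap(other)

        def bw(g):
            self._accumulate(g)
            other._accumulate(g)

        return _node(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return _node(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)

        def bw(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)

        return _node(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)

        def bw(g):
            self._accumulate(g / other.data)
            other._accumulate(-g * self.data / (other.data ** 2))

        return _node(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return _wrap(other) / self

    def __pow__(self, p: float):
        def bw(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return _node(self.data ** p, (self,), bw)

    def __matmul__(self, other):
        other = _wrap(other)

        def bw(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        return _node(self.data @ other.data, (self, other), bw)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return _node(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise functions ---------------------------------------------
    def exp(self):
        out = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out)

        return _node(out, (self,), bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)

        return _node(np.log(self.data), (self,), bw)

    def log1p(self):
        def bw(g):
            self._accumulate(g / (1.0 + self.data))

        return _node(np.log1p(self.data), (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accumulate(g * mask)

        return _node(self.data * mask, (self,), bw)

    def sigmoid(self):
        out = special.expit(self.data)

        def bw(g):
            self._accumulate(g * out * (1.0 - out))

        return _node(out, (self,), bw)

    def softplus(self):
        out = np.logaddexp(0.0, self.data)

        def bw(g):
            self._accumulate(g * special.expit(self.data))

        return _node(out, (self,), bw)

    def lgamma(self):
        def bw(g):
            self._accumulate(g * special.digamma(self.data))

        return _node(special.gammaln(self.data), (self,), bw)

    def abs(self):
        sign = np.sign(self.data)

        def bw(g):
            self._accumulate(g * sign)

        return _node(np.abs(self.data), (self,), bw)

    def clip(self, lo, hi):
        mask = (self.data > lo) & (self.data < hi)

        def bw(g):
            self._accumulate(g * mask)

        return _node(np.clip(self.data, lo, hi), (self,), bw)

    def reshape(self, *shape):
        old = self.data.shape

        def bw(g):
            self._accumulate(g.reshape(old))

        return _node(self.data.reshape(*shape), (self,), bw)

    @property
    def T(self):
        def bw(g):
            self._accumulate(g.T)

        return _node(self.data.T, (self,), bw)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    if any(p.requires_grad or p._parents for p in parents):
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


def where(mask: np.ndarray, a, b) -> Tensor:
    """Elementwise select with a constant (non-differentiable) mask."""
    a, b = _wrap(a), _wrap(b)
    mask = np.asarray(mask, dtype=bool)

    def bw(g):
        a._accumulate(g * mask)
        b._accumulate(g * (~mask))

    return _node(np.where(mask, a.data, b.data), (a, b), bw)


def logaddexp(a, b) -> Tensor:
    """Numerically stable log(exp(a)+exp(b)); the max is treated as constant,
    which leaves both the value and the gradient exact."""
    a, b = _wrap(a), _wrap(b)
    c = np.maximum(a.data, b.data)
    return Tensor(c) + ((a - c).exp() + (b - c).exp()).log()


def log_softmax(logits: Tensor, axis: int = -1) -> Tensor:
    c = logits.data.max(axis=axis, keepdims=True)
    shifted = logits - Tensor(c)
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


# ---------------------------------------------------------------------------
# layers and optimisation
# ---------------------------------------------------------------------------


class Dense:
    """Fully connected layer, Glorot-uniform initialised."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float64):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)).astype(dtype),
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        return x @ self.W.data + self.b.data

    @property
    def params(self):
        return [self.W, self.b]


class MLP:
    """Stack of Dense layers with ReLU between them; linear final layer."""

    def __init__(self, sizes: list[int], rng: np.random.Generator, dtype=np.float64):
        self.sizes = list(sizes)
        self.dtype = dtype
        self.layers = [Dense(a, b, rng, dtype=dtype) for a, b in zip(sizes[:-1], sizes[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        for i, layer in enumerate(self.layers):
            x = layer.forward_np(x)
            if i < len(self.layers) - 1:
                x = np.maximum(x, 0.0)
        return x

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            if p.data.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.data.shape} vs {w.shape}")
            p.data = w.astype(self.dtype)

    def copy(self) -> "MLP":
        clone = MLP(self.sizes, np.random.default_rng(0), dtype=self.dtype)
        clone.set_weights(self.get_weights())
        return clone


def save_mlp(mlp: MLP, path) -> None:
    """Persist an MLP's sizes and weights to an .npz archive."""
    arrays = {f"w{i}": w for i, w in enumerate(mlp.get_weights())}
    arrays["sizes"] = np.asarray(mlp.sizes)
    arrays["float32"] = np.asarray(mlp.dtype == np.float32)
    np.savez(path, **arrays)


def load_mlp(path) -> MLP:
    with np.load(path) as data:
        dtype = np.float32 if bool(data["float32"]) else np.float64
        mlp = MLP([int(s) for s in data["sizes"]], np.random.default_rng(0), dtype=dtype)
        mlp.set_weights([data[f"w{i}"] for i in range(len(mlp.params))])
    return mlp


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        # bias-corrected step size folded into a scalar (standard trick)
        alpha = self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            m, v = self.m[i], self.v[i]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            denom = np.sqrt(v)
            denom += self.eps
            p.data -= alpha * m / denom

    def zero_grad(self):
        for p in self.params:
            p.grad = None
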