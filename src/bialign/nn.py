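"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the bilateral contrastive autoencoder
needs: broadcast arithmetic, matmul, reductions, exp/log/sqrt, LeakyReLU,
softplus, row/column gathers, a numerically stable log-sum-exp, batch
normalization, dropout, and an Adam optimizer with L2 weight decay.
Gradients are accumulated by topological-order backpropagation; every
gradient is validated against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing over broadcast axes."""
    grad = np.asarray(grad)
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an attached backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.requires_grad = bool(requires_grad or any(p.requires_grad for p in parents))
        self.grad = None
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph traversal -------------------------------------------------
    def backward(self, grad=None) -> None:
        if not self.requires_grad:
            raise RuntimeError("called backward on a tensor that requires no grad")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if p.requires_grad and id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad = parent.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # -- convenience -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        return Tensor(self.data + other.data, parents=(self, other),
                      backward=lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        return Tensor(self.data * other.data, parents=(self, other),
                      backward=lambda g: (_unbroadcast(g * other.data, self.shape),
                                          _unbroadcast(g * self.data, other.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return Tensor(self.data / other.data, parents=(self, other),
                      backward=lambda g: (_unbroadcast(g / other.data, self.shape),
                                          _unbroadcast(-g * self.data / other.data ** 2, other.shape)))

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        return Tensor(self.data ** exponent, parents=(self,),
                      backward=lambda g: (g * exponent * self.data ** (exponent - 1),))

    def __matmul__(self, other):
        other = self._wrap(other)
        return Tensor(self.data @ other.data, parents=(self, other),
                      backward=lambda g: (g @ other.data.T, self.data.T @ g))

    @property
    def T(self):
        return Tensor(self.data.T, parents=(self,), backward=lambda g: (g.T,))

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def back(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            ge = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(ge, self.shape).copy(),)
        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=back)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise -----------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor(out_data, parents=(self,), backward=lambda g: (g * out_data,))

    def log(self):
        return Tensor(np.log(self.data), parents=(self,), backward=lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor(out_data, parents=(self,), backward=lambda g: (g * 0.5 / out_data,))

    def leaky_relu(self, negative_slope: float = 0.2):
        mask = np.where(self.data > 0, 1.0, negative_slope)
        return Tensor(self.data * mask, parents=(self,), backward=lambda g: (g * mask,))

    def softplus(self):
        # stable: log(1 + exp(x)) = max(x, 0) + log1p(exp(-|x|))
        out_data = np.maximum(self.data, 0) + np.log1p(np.exp(-np.abs(self.data)))
        sig = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(out_data, parents=(self,), backward=lambda g: (g * sig,))

    # -- indexing --------------------------------------------------------
    def take_rows(self, rows: np.ndarray):
        rows = np.asarray(rows, dtype=int)

        def back(g):
            out = np.zeros_like(self.data)
            np.add.at(out, rows, g)
            return (out,)

        return Tensor(self.data[rows], parents=(self,), backward=back)

    def gather(self, rows: np.ndarray, cols: np.ndarray):
        rows = np.asarray(rows, dtype=int)
        cols = np.asarray(cols, dtype=int)

        def back(g):
            out = np.zeros_like(self.data)
            np.add.at(out, (rows, cols), g)
            return (out,)

        return Tensor(self.data[rows, cols], parents=(self,), backward=back)

    def logsumexp(self, axis: int = 1):
        m = self.data.max(axis=axis, keepdims=True)
        ex = np.exp(self.data - m)
        s = ex.sum(axis=axis, keepdims=True)
        out_data = np.squeeze(m + np.log(s), axis=axis)

        def back(g):
            soft = ex / s
            return (np.expand_dims(g, axis) * soft,)

        return Tensor(out_data, parents=(self,), backward=back)

    def normalize_rows(self, eps: float = 1e-12):
        """Unit-L2-normalize each row (for cosine similarities)."""
        sq = (self * self).sum(axis=1, keepdims=True)
        return self / (sq + eps).sqrt()


# ---------------------------------------------------------------------------
# layers


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        gain = np.sqrt(2.0 / (1.0 + 0.2 ** 2))  # LeakyReLU(0.2) Kaiming gain
        self.weight = Parameter(rng.standard_normal((n_in, n_out)) * gain / np.sqrt(n_in))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def parameters(self):
        return [self.weight, self.bias]


class BatchNorm1d:
    """Batch normalization with running statistics for deterministic inference."""

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(n))
        self.beta = Parameter(np.zeros(n))
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
            return self.gamma * ((x - mu) / (var + self.eps).sqrt()) + self.beta
        xhat = (x - Tensor(self.running_mean)) / Tensor(np.sqrt(self.running_var + self.eps))
        return self.gamma * xhat + self.beta

    def parameters(self):
        return [self.gamma, self.beta]


class Dropout:
    def __init__(self, rate: float):
        self.rate = rate

    def __call__(self, x: Tensor, training: bool, rng: np.random.Generator) -> Tensor:
        if not training or self.rate == 0.0:
            return x
        keep = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(keep)


class MLPEncoder:
    """Two hidden blocks of linear -> batchnorm -> LeakyReLU -> dropout, then linear."""

    def __init__(self, n_in: int, hidden: tuple[int, ...], n_out: int,
                 rng: np.random.Generator, negative_slope: float = 0.2, dropout: float = 0.2):
        self.blocks = []
        prev = n_in
        for h in hidden:
            self.blocks.append((Linear(prev, h, rng), BatchNorm1d(h), Dropout(dropout)))
            prev = h
        self.head = Linear(prev, n_out, rng)
        self.negative_slope = negative_slope

    def __call__(self, x: Tensor, training: bool, rng: np.random.Generator) -> Tensor:
        for lin, bn, drop in self.blocks:
            x = bn(lin(x), training).leaky_relu(self.negative_slope)
            x = drop(x, training, rng)
        return self.head(x)

    def parameters(self):
        out = []
        for lin, bn, _ in self.blocks:
            out += lin.parameters() + bn.parameters()
        return out + self.head.parameters()


class Adam:
    """Adam with L2 weight decay added to the gradient."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
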