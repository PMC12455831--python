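"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine providing exactly the operations the graph
attention autoencoder and the complex-valued knowledge-graph embedding
need: broadcast arithmetic, matrix products, reductions, elementwise
nonlinearities, integer-row gathering and concatenation, plus an Adam
optimizer. Everything runs in float64.

Gradient correctness is enforced by finite-difference tests in the test
suite; no approximation is used anywhere in the backward passes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "concat", "gather"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Node in the computation graph.

    Wraps a float64 ndarray; records parents and a backward closure when
    produced by an operation on tensors that require gradients.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run reverse accumulation from this (typically scalar) node."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- constructors ------------------------------------------------------

    @staticmethod
    def _make(data, parents, backward, requires_grad):
        out = Tensor(data, requires_grad=requires_grad)
        if requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = Tensor._wrap(other)
        rq = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward, rq)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward, self.requires_grad)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        rq = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward, rq)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        rq = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward, rq)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) / self

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        rq = self.requires_grad or other.requires_grad
        A, B = self.data, other.data
        if A.ndim > 2 or B.ndim > 2:
            raise ValueError("matmul supports 1-D and 2-D operands only")

        def backward(g):
            if self.requires_grad:
                if A.ndim == 2 and B.ndim == 2:
                    self._accumulate(g @ B.T)
                elif A.ndim == 2:          # (n,m) @ (m,) -> (n,)
                    self._accumulate(np.outer(g, B))
                elif B.ndim == 2:          # (m,) @ (m,p) -> (p,)
                    self._accumulate(B @ g)
                else:                      # (m,) @ (m,) -> scalar
                    self._accumulate(g * B)
            if other.requires_grad:
                if A.ndim == 2 and B.ndim == 2:
                    other._accumulate(A.T @ g)
                elif A.ndim == 2:
                    other._accumulate(A.T @ g)
                elif B.ndim == 2:
                    other._accumulate(np.outer(A, g))
                else:
                    other._accumulate(g * A)

        return Tensor._make(A @ B, (self, other), backward, rq)

    def __pow__(self, p: float):
        p = float(p)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1.0))

        return Tensor._make(self.data**p, (self,), backward, self.requires_grad)

    # -- reshaping / indexing ---------------------------------------------

    @property
    def T(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g.T)

        return Tensor._make(self.data.T, (self,), backward, self.requires_grad)

    def reshape(self, *shape):
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (self,), backward,
                            self.requires_grad)

    def __getitem__(self, key):
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accumulate(full)

        return Tensor._make(self.data[key], (self,), backward, self.requires_grad)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), backward, self.requires_grad)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward, self.requires_grad)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def softplus(self):
        # log(1 + e^x), computed stably; derivative is sigmoid(x)
        out_data = np.logaddexp(0.0, self.data)

        def backward(g):
            if self.requires_grad:
                sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
                self._accumulate(g * sig)

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def leaky_relu(self, negative_slope: float = 0.2):
        slope = float(negative_slope)
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * np.where(mask, 1.0, slope))

        return Tensor._make(np.where(mask, self.data, slope * self.data),
                            (self,), backward, self.requires_grad)

    def prelu(self, alpha: "Tensor"):
        """PReLU with a learnable (scalar) slope for the negative part."""
        mask = self.data > 0
        a = alpha.data
        out_data = np.where(mask, self.data, a * self.data)
        rq = self.requires_grad or alpha.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * np.where(mask, 1.0, a))
            if alpha.requires_grad:
                alpha._accumulate(
                    _unbroadcast(g * np.where(mask, 0.0, self.data), alpha.data.shape)
                )

        return Tensor._make(out_data, (self, alpha), backward, rq)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A Tensor that always participates in gradient accumulation."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along `axis` with gradient routing."""
    tensors = [Tensor._wrap(t) for t in tensors]
    rq = any(t.requires_grad for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, backward, rq)


def gather(t: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather t[idx] with scatter-add backward (duplicate indices sum)."""
    return t[np.asarray(idx, dtype=np.intp)]


class Adam:
    """Adam optimizer over a flat list of Parameters."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
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

    def state_dict(self) -> dict:
        return {"t": self.t,
                "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(m, dtype=np.float64).copy() for m in state["m"]]
        self.v = [np.asarray(v, dtype=np.float64).copy() for v in state["v"]]
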