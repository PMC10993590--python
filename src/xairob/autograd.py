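"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A small tape-based autodiff engine sufficient for transformer encoders and
their attribution methods: broadcast-aware arithmetic, (batched) matrix
multiplication, softmax, layer normalisation building blocks, embedding
lookup, fancy-index gather and 1-D convolution.  Gradients are accumulated
on every node of the tape, so callers can read gradients of *intermediate*
quantities (e.g. attention matrices) after a single backward pass — the
property the attribution methods rely on.

The engine is deliberately eager and single-threaded; determinism follows
from NumPy's.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable tape construction inside the block (forward-only passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum `grad` down to `shape`, inverting NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node on the autodiff tape wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[Array], Sequence[Array | None]] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self.requires_grad = (
            requires_grad or any(p.requires_grad for p in parents)
        ) and _GRAD_ENABLED
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- infrastructure -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: Array | None = None) -> None:
        """Backpropagate from this node; grads accumulate on every node."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if pgrad is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = pgrad.copy()
                else:
                    parent.grad = parent.grad + pgrad

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(
            self.data + other.data,
            parents=(self, other),
            backward=lambda g: (
                _unbroadcast(g, self.shape),
                _unbroadcast(g, other.shape),
            ),
        )
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor(-self.data, parents=(self,), backward=lambda g: (-g,))

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        return Tensor(
            self.data * other.data,
            parents=(self, other),
            backward=lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        return Tensor(
            self.data / other.data,
            parents=(self, other),
            backward=lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        return Tensor(
            self.data**exponent,
            parents=(self,),
            backward=lambda g: (g * exponent * self.data ** (exponent - 1),),
        )

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bwd(g: Array):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return Tensor(self.data @ other.data, parents=(self, other), backward=bwd)

    def __getitem__(self, idx) -> "Tensor":
        def bwd(g: Array):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor(self.data[idx], parents=(self,), backward=bwd)

    # -- reductions & shaping ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bwd(g: Array):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=bwd
        )

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis] if isinstance(axis, int) else int(
                np.prod([self.data.shape[a] for a in axis])
            )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out_data).astype(np.float64)
        mask /= mask.sum(axis=axis, keepdims=True)  # split ties evenly

        def bwd(g: Array):
            gg = g if keepdims else np.expand_dims(g, axis)
            return (mask * gg,)

        return Tensor(
            out_data if keepdims else out_data.squeeze(axis),
            parents=(self,),
            backward=bwd,
        )

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor(
            self.data.reshape(shape),
            parents=(self,),
            backward=lambda g: (g.reshape(self.shape),),
        )

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor(
            self.data.transpose(axes),
            parents=(self,),
            backward=lambda g: (g.transpose(inv),),
        )

    # -- nonlinearities ----------------------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)
        return Tensor(out_data, parents=(self,), backward=lambda g: (g * out_data,))

    def log(self) -> "Tensor":
        return Tensor(
            np.log(self.data), parents=(self,), backward=lambda g: (g / self.data,)
        )

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)
        return Tensor(
            out_data, parents=(self,), backward=lambda g: (g * (1 - out_data**2),)
        )

    def relu(self) -> "Tensor":
        mask = (self.data > 0).astype(np.float64)
        return Tensor(self.data * mask, parents=(self,), backward=lambda g: (g * mask,))

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(
            out_data,
            parents=(self,),
            backward=lambda g: (g * out_data * (1 - out_data),),
        )

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bwd(g: Array):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            return (out_data * (g - dot),)

        return Tensor(out_data, parents=(self,), backward=bwd)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g: Array):
        slicer = [slice(None)] * g.ndim
        grads = []
        for i in range(len(datas)):
            slicer[axis] = slice(offsets[i], offsets[i + 1])
            grads.append(g[tuple(slicer)])
        return grads

    return Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors), backward=bwd)


def embedding_lookup(table: Tensor, ids: Array) -> Tensor:
    """Gather rows of `table` (V, E) by an integer array `ids` (...,)."""
    ids = np.asarray(ids, dtype=np.intp)

    def bwd(g: Array):
        full = np.zeros_like(table.data)
        np.add.at(full, ids.reshape(-1), g.reshape(-1, table.shape[-1]))
        return (full,)

    return Tensor(table.data[ids], parents=(table,), backward=bwd)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Valid-mode 1-D convolution over the sequence axis.

    x: (B, S, E); weight: (k, E, F); bias: (F,) -> (B, S-k+1, F).
    """
    k = weight.shape[0]
    B, S, E = x.shape
    F = weight.shape[2]
    L = S - k + 1
    if L < 1:
        raise ValueError(f"sequence length {S} shorter than kernel {k}")
    # im2col: windows (B, L, k*E)
    idx = np.arange(L)[:, None] + np.arange(k)[None, :]  # (L, k)
    cols = x.data[:, idx, :].reshape(B, L, k * E)
    w2 = weight.data.reshape(k * E, F)
    out_data = cols @ w2 + bias.data

    def bwd(g: Array):
        gw = (cols.reshape(B * L, k * E).T @ g.reshape(B * L, F)).reshape(k, E, F)
        gb = g.sum(axis=(0, 1))
        gcols = (g @ w2.T).reshape(B, L, k, E)
        gx = np.zeros((B, S, E))
        np.add.at(gx, (slice(None), idx, slice(None)), gcols)
        return gx, gw, gb

    return Tensor(out_data, parents=(x, weight, bias), backward=bwd)


# ---------------------------------------------------------------------------
# parameters and optimisation


class Parameter(Tensor):
    """A leaf tensor updated by an optimiser."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Array:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class AdamW:
    """AdamW with decoupled weight decay (bias/gain tensors included)."""

    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            mhat = self._m[i] / (1 - b1**self.t)
            vhat = self._v[i] / (1 - b2**self.t)
            p.data -= self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data
            )
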