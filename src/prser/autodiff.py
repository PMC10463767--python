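"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A tape-based scalar/tensor autodiff sized for the small transformer encoder
in this package: broadcasting-aware elementwise ops, (batched) matmul,
reductions, indexing/gather, and the handful of nonlinearities a BERT-style
block needs. Float64 throughout — gradient checks against finite differences
are part of the package's test contract and float32 is too coarse for them.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concatenate", "stack", "logsumexp", "softmax",
           "layer_norm", "gelu", "tanh"]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def _send(acc: dict[int, np.ndarray], parent: "Tensor", g: np.ndarray) -> None:
    """Route a gradient contribution to `parent` during backward.

    Leaf parameters accumulate into ``.grad``; interior nodes accumulate in
    the driver's dict. Module-level on purpose: backward closures must not
    reference the node they belong to, or every op would create a reference
    cycle and graph memory would only be reclaimed by the cycle collector.
    """
    if not parent.requires_grad:
        return
    if parent._backward is None and not parent._parents:
        parent.grad = g if parent.grad is None else parent.grad + g
        return
    key = id(parent)
    acc[key] = g if key not in acc else acc[key] + g


class Tensor:
    """An n-d array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None
        self.name = name

    # ---- construction helpers -------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # ---- autodiff driver -------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order, iterative to survive deep graphs
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                node._backward(g, grads)
            elif node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g

    # ---- elementwise arithmetic -----------------------------------------
    def __add__(self, other) -> "Tensor":
        other = self._lift(other)

        def back(g, acc):
            _send(acc, self, _unbroadcast(g, self.shape))
            _send(acc, other, _unbroadcast(g, other.shape))

        out = self._make(self.data + other.data, (self, other), back)
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def back(g, acc):
            _send(acc, self, -g)

        out = self._make(-self.data, (self,), back)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)

        def back(g, acc):
            _send(acc, self, _unbroadcast(g * other.data, self.shape))
            _send(acc, other, _unbroadcast(g * self.data, other.shape))

        out = self._make(self.data * other.data, (self, other), back)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)

        def back(g, acc):
            _send(acc, self, _unbroadcast(g / other.data, self.shape))
            _send(acc, other, _unbroadcast(-g * self.data / other.data ** 2, other.shape))

        out = self._make(self.data / other.data, (self, other), back)
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        if isinstance(exponent, Tensor):
            raise TypeError("tensor exponents unsupported")

        def back(g, acc):
            _send(acc, self, g * exponent * self.data ** (exponent - 1))

        out = self._make(self.data ** exponent, (self,), back)
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)

        def back(g, acc):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            _send(acc, self, _unbroadcast(ga, self.shape))
            _send(acc, other, _unbroadcast(gb, other.shape))

        out = self._make(self.data @ other.data, (self, other), back)
        return out

    # ---- shaping ---------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def back(g, acc):
            _send(acc, self, g.reshape(self.shape))

        out = self._make(self.data.reshape(shape), (self,), back)
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        def back(g, acc):
            _send(acc, self, np.swapaxes(g, a, b))

        out = self._make(np.swapaxes(self.data, a, b), (self,), back)
        return out

    def __getitem__(self, key) -> "Tensor":
        def back(g, acc):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            _send(acc, self, full)

        out = self._make(self.data[key], (self,), back)
        return out

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def back(g, acc):
            if axis is None:
                _send(acc, self, np.broadcast_to(g, self.shape).copy())
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            _send(acc, self, np.broadcast_to(gg, self.shape).copy())

        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), back)
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def amax(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Max along one axis; gradient flows to the (first) argmax positions."""
        idx = np.argmax(self.data, axis=axis)

        def back(g, acc):
            gg = g if keepdims else np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), gg, axis=axis)
            _send(acc, self, full)

        out = self._make(self.data.max(axis=axis, keepdims=keepdims), (self,), back)
        return out

    # ---- nonlinearities --------------------------------------------------
    def exp(self) -> "Tensor":
        val = np.exp(self.data)

        def back(g, acc):
            _send(acc, self, g * val)

        out = self._make(val, (self,), back)
        return out

    def log(self) -> "Tensor":
        def back(g, acc):
            _send(acc, self, g / self.data)

        out = self._make(np.log(self.data), (self,), back)
        return out

    def sqrt(self) -> "Tensor":
        val = np.sqrt(self.data)

        def back(g, acc):
            _send(acc, self, g * 0.5 / val)

        out = self._make(val, (self,), back)
        return out

    def tanh(self) -> "Tensor":
        val = np.tanh(self.data)

        def back(g, acc):
            _send(acc, self, g * (1.0 - val ** 2))

        out = self._make(val, (self,), back)
        return out

    def abs(self) -> "Tensor":
        def back(g, acc):
            _send(acc, self, g * np.sign(self.data))

        out = self._make(np.abs(self.data), (self,), back)
        return out

    def gelu(self) -> "Tensor":
        """Exact (erf-based) GELU."""
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / _SQRT2))
        val = x * cdf

        def back(g, acc):
            pdf = _INV_SQRT_2PI * np.exp(-0.5 * x ** 2)
            _send(acc, self, g * (cdf + x * pdf))

        out = self._make(val, (self,), back)
        return out

    def __repr__(self) -> str:  # pragma: no cover
        tag = f" name={self.name}" if self.name else ""
        return f"Tensor(shape={self.shape}, grad={self.requires_grad}{tag})"


# ---- free functions -------------------------------------------------------

def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g, acc):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _send(acc, t, piece)

    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = back
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = Tensor._lift(t)
        expanded.append(t.reshape(t.shape[:axis] + (1,) + t.shape[axis:]))
    return concatenate(expanded, axis=axis)


def softmax(x: Tensor, axis: int = -1, mask: np.ndarray | None = None) -> Tensor:
    """Softmax along `axis`; positions where ``mask == 0`` get zero weight.

    Fused forward/backward (one node on the tape): attention weight arrays
    are the largest tensors in the encoder and composing this from
    elementwise ops would allocate half a dozen same-sized temporaries.
    """
    data = x.data
    if mask is not None:
        mask = np.asarray(mask, dtype=np.float64)
        if not np.all(mask.max(axis=axis) > 0):
            raise ValueError("softmax mask leaves no attendable position in some row")
        data = np.where(mask > 0, data, -np.inf)
    shifted = data - data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def back(g, acc):
        dot = (g * s).sum(axis=axis, keepdims=True)
        _send(acc, x, _unbroadcast(s * (g - dot), x.shape))

    out = x._make(s, (x,), back)
    return out


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-12) -> Tensor:
    """Layer normalization over the last axis, fused into one tape node."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    val = gain.data * xhat + bias.data

    def back(g, acc):
        dg_xhat = g * gain.data
        n = x.data.shape[-1]
        term = (dg_xhat - dg_xhat.mean(axis=-1, keepdims=True)
                - xhat * (dg_xhat * xhat).mean(axis=-1, keepdims=True))
        _send(acc, x, term * inv_std)
        _send(acc, gain, _unbroadcast(g * xhat, gain.shape))
        _send(acc, bias, _unbroadcast(g, bias.shape))

    out = x._make(val, (x, gain, bias), back)
    return out


def logsumexp(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    shift_np = np.max(x.data, axis=axis, keepdims=True)
    shift = Tensor(shift_np)
    s = ((x - shift).exp()).sum(axis=axis, keepdims=True).log() + shift
    if not keepdims and axis is not None:
        s = s.reshape(np.squeeze(s.data, axis=axis).shape)
    elif not keepdims and axis is None:
        s = s.reshape(())
    return s


def tanh(x: Tensor) -> Tensor:
    return x.tanh()


def gelu(x: Tensor) -> Tensor:
    return x.gelu()


def parameters(tree) -> list[Tensor]:
    """Flatten a (possibly nested) dict of Tensors into a list."""
    if isinstance(tree, Tensor):
        return [tree]
    out: list[Tensor] = []
    if isinstance(tree, dict):
        for key in sorted(tree):
            out.extend(parameters(tree[key]))
    elif isinstance(tree, (list, tuple)):
        for item in tree:
            out.extend(parameters(item))
    return out
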