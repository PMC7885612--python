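"""Minimal reverse-mode automatic differentiation over numpy arrays.

The networks in this package (LSTM temporal encoder, label-aware attention
CNN, fused sigmoid head) are small enough that a tape-based scalar-loss
autodiff engine over dense numpy tensors is both fast and transparent.  The
engine supports exactly the operations those models need: broadcasting
arithmetic, (batched) matmul, reductions, pointwise nonlinearities, gather
(embedding lookup), concatenation and a 'same'-padded 1-D convolution.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`;
correctness is pinned down by finite-difference tests rather than by trusting
any one derivation.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "conv1d", "take"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the local backward rule that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        a, b = self, Tensor._lift(other)

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accum(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return Tensor._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        a = self
        p = float(exponent)

        def backward(g):
            a._accum(g * p * a.data ** (p - 1.0))

        return Tensor._make(a.data ** p, (a,), backward)

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)

        def backward(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accum(_unbroadcast(gb, b.shape))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along ``axis``; ties share the gradient equally."""
        a = self
        out = a.data.max(axis=axis, keepdims=True)
        mask = (a.data == out).astype(np.float64)
        mask /= mask.sum(axis=axis, keepdims=True)

        def backward(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            a._accum(mask * gg)

        data = out if keepdims else np.squeeze(out, axis=axis)
        return Tensor._make(data, (a,), backward)

    # -- pointwise nonlinearities ---------------------------------------------
    def relu(self):
        a = self
        mask = (a.data > 0).astype(np.float64)

        def backward(g):
            a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), backward)

    def sigmoid(self):
        a = self
        out = np.empty_like(a.data)
        pos = a.data >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
        ex = np.exp(a.data[~pos])
        out[~pos] = ex / (1.0 + ex)

        def backward(g):
            a._accum(g * out * (1.0 - out))

        return Tensor._make(out, (a,), backward)

    def tanh(self):
        a = self
        out = np.tanh(a.data)

        def backward(g):
            a._accum(g * (1.0 - out ** 2))

        return Tensor._make(out, (a,), backward)

    def exp(self):
        a = self
        out = np.exp(a.data)

        def backward(g):
            a._accum(g * out)

        return Tensor._make(out, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), backward)

    def sqrt(self):
        a = self
        out = np.sqrt(a.data)

        def backward(g):
            a._accum(g * 0.5 / out)

        return Tensor._make(out, (a,), backward)

    def clip(self, lo: float, hi: float):
        a = self
        mask = ((a.data > lo) & (a.data < hi)).astype(np.float64)

        def backward(g):
            a._accum(g * mask)

        return Tensor._make(np.clip(a.data, lo, hi), (a,), backward)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        a = self
        old = a.shape

        def backward(g):
            a._accum(g.reshape(old))

        return Tensor._make(a.data.reshape(*shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        axes_ = axes or tuple(reversed(range(a.ndim)))
        inv = np.argsort(axes_)

        def backward(g):
            a._accum(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes_), (a,), backward)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor._make(a.data[idx], (a,), backward)

    # -- bookkeeping ----------------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backprop from this (scalar) tensor through the recorded tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    parts = [Tensor._lift(t) for t in tensors]
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                p._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([p.data for p in parts], axis=axis), parts, backward)


def take(weight: Tensor, indices: np.ndarray) -> Tensor:
    """Row gather, e.g. embedding lookup: ``weight[indices]`` for an index array."""
    w = Tensor._lift(weight)
    idx = np.asarray(indices, dtype=np.int64)

    def backward(g):
        gw = np.zeros_like(w.data)
        np.add.at(gw, idx, g)
        w._accum(gw)

    return Tensor._make(w.data[idx], (w,), backward)


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """'Same'-padded 1-D convolution (cross-correlation).

    x: (B, L, C_in); w: (C_out, s, C_in); b: (C_out,) -> (B, L, C_out).
    Zero padding keeps the output length equal to L for any filter size s
    (left pad (s-1)//2, right pad s//2), so sequences shorter than the filter
    are handled by the same zero-padding rule.
    """
    x, w = Tensor._lift(x), Tensor._lift(w)
    cout, s, cin = w.shape
    lpad, rpad = (s - 1) // 2, s // 2
    B, L, _ = x.shape
    xp = np.pad(x.data, ((0, 0), (lpad, rpad), (0, 0)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, s, axis=1)  # (B,L,Cin,s)
    out = np.einsum("blcs,osc->blo", windows, w.data, optimize=True)
    parents = [x, w]
    if b is not None:
        b = Tensor._lift(b)
        out = out + b.data
        parents.append(b)

    def backward(g):
        if w.requires_grad:
            w._accum(np.einsum("blcs,blo->osc", windows, g, optimize=True))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for j in range(s):
                gxp[:, j : j + L, :] += np.einsum("blo,oc->blc", g, w.data[:, j, :], optimize=True)
            x._accum(gxp[:, lpad : lpad + L, :])
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 1)))

    return Tensor._make(out, parents, backward)


class Adam:
    """Adam optimizer over a dict of named parameter tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            m = self._m[k]
            v = self._v[k]
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
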