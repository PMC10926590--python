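"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the fusion network needs: broadcasting
arithmetic, matmul, elementwise nonlinearities, reductions, reshape/concat,
and strided depthwise / pointwise 3-D convolution.  Gradients are accumulated
by topological traversal of the recorded graph.  float64 throughout; the
package trades memory for exact run-to-run reproducibility on CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "depthwise_conv3d", "pointwise_conv3d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes that broadcasting added or expanded."""
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
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._vjps: tuple = ()

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _make(data, parents, vjps) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._vjps = tuple(vjps)
        return out

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        return Tensor._make(
            self.data + other.data,
            (self, other),
            (
                lambda g: _unbroadcast(g, self.shape),
                lambda g: _unbroadcast(g, other.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), (lambda g: -g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            (
                lambda g: _unbroadcast(g * other.data, self.shape),
                lambda g: _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        return Tensor._make(
            self.data ** p,
            (self,),
            (lambda g: g * p * self.data ** (p - 1),),
        )

    def __matmul__(self, other):
        other = self._wrap(other)
        return Tensor._make(
            self.data @ other.data,
            (self, other),
            (
                lambda g: g @ other.data.T,
                lambda g: self.data.T @ g,
            ),
        )

    # -- nonlinearities -----------------------------------------------------

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), (lambda g: g * mask,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return Tensor._make(s, (self,), (lambda g: g * s * (1.0 - s),))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), (lambda g: g / self.data,))

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        return Tensor._make(
            np.clip(self.data, lo, hi), (self,), (lambda g: g * mask,)
        )

    # -- reductions and shaping ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def vjp(g):
            if axis is None:
                return np.broadcast_to(g, self.shape).copy()
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.shape).copy()

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), (vjp,))

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), (lambda g: g.reshape(src),)
        )

    def __getitem__(self, idx):
        def vjp(g):
            out = np.zeros(self.shape)
            out[idx] = g
            return out

        return Tensor._make(self.data[idx], (self,), (vjp,))

    # -- backward -----------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
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
            for parent, vjp in zip(node._parents, node._vjps):
                if not parent.requires_grad:
                    continue
                contrib = vjp(node.grad)
                if parent.grad is None:
                    parent.grad = contrib
                else:
                    parent.grad = parent.grad + contrib

    def zero_grad(self):
        self.grad = None


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        def vjp(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offsets[i], offsets[i + 1])
            return g[tuple(sl)]

        return vjp

    return Tensor._make(data, tensors, tuple(make_vjp(i) for i in range(len(tensors))))


# -- 3-D convolution primitives -----------------------------------------------
#
# Layout: x is (N, C, D, H, W); depthwise weights are (C, k, k, k); pointwise
# weights are (C_out, C_in).  'same' padding keeps ceil(dim/stride).


def _pad_same(x: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    p = (k - 1) // 2
    q = k - 1 - p
    return np.pad(x, ((0, 0), (0, 0), (p, q), (p, q), (p, q))), p


def depthwise_conv3d(x: Tensor, w: Tensor, stride: int = 1) -> Tensor:
    """Per-channel k^3 convolution (correlation), 'same' padding."""
    k = w.shape[-1]
    xp, _ = _pad_same(x.data, k)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    win = win[:, :, ::stride, ::stride, ::stride]
    out = np.einsum("ncdhwijk,cijk->ncdhw", win, w.data, optimize=True)

    def vjp_x(g):
        gx = np.zeros_like(xp)
        D, H, W = g.shape[2:]
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    gx[
                        :,
                        :,
                        i : i + stride * D : stride,
                        j : j + stride * H : stride,
                        l : l + stride * W : stride,
                    ] += g * w.data[None, :, i, j, l, None, None, None]
        p = (k - 1) // 2
        q = k - 1 - p
        sl = lambda a, b: slice(a, None if b == 0 else -b)  # noqa: E731
        return gx[:, :, sl(p, q), sl(p, q), sl(p, q)]

    def vjp_w(g):
        return np.einsum("ncdhwijk,ncdhw->cijk", win, g, optimize=True)

    return Tensor._make(out, (x, w), (vjp_x, vjp_w))


def pointwise_conv3d(x: Tensor, w: Tensor) -> Tensor:
    """1x1x1 channel-mixing convolution; w is (C_out, C_in)."""
    out = np.einsum("ncdhw,oc->nodhw", x.data, w.data, optimize=True)

    def vjp_x(g):
        return np.einsum("nodhw,oc->ncdhw", g, w.data, optimize=True)

    def vjp_w(g):
        return np.einsum("nodhw,ncdhw->oc", g, x.data, optimize=True)

    return Tensor._make(out, (x, w), (vjp_x, vjp_w))
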