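"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations applied
to it; :meth:`Tensor.backward` runs reverse-mode accumulation over the
recorded graph.  The op set is exactly what the segmentation networks in this
package need: broadcasting arithmetic, batched matmul, 2-D convolution
(stride 1, zero padding), 2x2 max pooling, nearest-neighbour 2x upsampling,
reductions, reshapes/transposes, concatenation and basic slicing.

All gradients are checked against central finite differences in the test
suite; the engine is deliberately small rather than general.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "conv2d", "maxpool2x2", "upsample2x"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.asarray(grad, dtype=np.float32)
        else:
            # out-of-place: the stored array may be a broadcast view
            self.grad = self.grad + grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- introspection -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g):
            if self.requires_grad:
                self._accum(g * e * self.data ** (e - 1.0))

        return Tensor._make(self.data**e, (self,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                ga = g @ other.data.swapaxes(-1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = self.data.swapaxes(-1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        return self**0.5

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        # stable two-sided form avoids overflow for large |x|
        x = self.data
        out_data = np.where(
            x >= 0,
            1.0 / (1.0 + np.exp(-np.abs(x))),
            np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))),
        ).astype(np.float32)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g
                if not keepdims:
                    gg = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.data.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, key):
        def backward(g):
            if self.requires_grad:
                dx = np.zeros_like(self.data)
                np.add.at(dx, key, g)
                self._accum(dx)

        return Tensor._make(self.data[key], (self,), backward)


class Parameter(Tensor):
    """A trainable tensor."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), stride 1, zero padding.

    x: (B, Cin, H, W); w: (Cout, Cin, kh, kw); b: (Cout,) or None.
    Uses direct compiled kernels; the padded input is retained for the
    backward pass.
    """
    from ._conv_kernels import conv_backward_input, conv_backward_weight, conv_forward

    B, cin, H, W = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, kernel {cin_w}")
    p = padding
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
        if p
        else np.ascontiguousarray(x.data)
    )
    out = conv_forward(xp, np.ascontiguousarray(w.data))
    if b is not None:
        out += b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g = np.ascontiguousarray(g)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accum(conv_backward_weight(g, xp, kh, kw))
        if x.requires_grad:
            dxp = conv_backward_input(g, np.ascontiguousarray(w.data), xp.shape[2], xp.shape[3])
            x._accum(dxp[:, :, p : p + H, p : p + W] if p else dxp)

    return Tensor._make(out, parents, backward)


def maxpool2x2(x: Tensor) -> Tensor:
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2x2 requires even spatial dims")
    Hh, Ww = H // 2, W // 2
    xr = x.data.reshape(B, C, Hh, 2, Ww, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        B, C, Hh, Ww, 4
    )
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dxr = np.zeros((B, C, Hh, Ww, 4), dtype=np.float32)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = dxr.reshape(B, C, Hh, Ww, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            B, C, H, W
        )
        x._accum(dx)

    return Tensor._make(out, (x,), backward)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    B, C, H, W = x.data.shape
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        if x.requires_grad:
            x._accum(g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)))

    return Tensor._make(out, (x,), backward)
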