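"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine provides exactly the primitives the staining networks need:
broadcast arithmetic, pointwise nonlinearities, reductions, zero-padded
strided convolution, average pooling, nearest-neighbour upsampling and
channel concatenation.  Gradients flow only into tensors created with
``requires_grad=True`` (parameters) or derived from them; fixed inputs
such as image batches and binary masks stay gradient-free.

Arrays keep whatever float dtype they are given, so loss arithmetic on
float64 inputs is exact to double precision while network parameters can
stay in float32 for speed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "pow_",
    "abs_",
    "relu",
    "leaky_relu",
    "tanh",
    "sum_",
    "mean_",
    "conv2d",
    "avg_pool2d",
    "upsample_nearest2d",
    "concat",
]


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    # operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return pow_(self, p)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ------------------------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from a scalar result through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in seen and p._needs_grad():
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent._needs_grad():
                    continue
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g

    def _needs_grad(self) -> bool:
        return self.requires_grad or self._backward is not None


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p._needs_grad() for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` to undo NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ----------------------------------------------------------------------
# arithmetic
# ----------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)),
    )


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data - b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(-g, b.data.shape)),
    )


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data * b.data,
        (a, b),
        lambda g: (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        ),
    )


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data / b.data,
        (a, b),
        lambda g: (
            _unbroadcast(g / b.data, a.data.shape),
            _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape),
        ),
    )


def neg(a) -> Tensor:
    a = as_tensor(a)
    return _node(-a.data, (a,), lambda g: (-g,))


def pow_(a, p: float) -> Tensor:
    a = as_tensor(a)
    return _node(a.data**p, (a,), lambda g: (g * p * a.data ** (p - 1),))


def abs_(a) -> Tensor:
    a = as_tensor(a)
    return _node(np.abs(a.data), (a,), lambda g: (g * np.sign(a.data),))


# ----------------------------------------------------------------------
# nonlinearities
# ----------------------------------------------------------------------

def relu(a) -> Tensor:
    a = as_tensor(a)
    out = np.maximum(a.data, 0)
    return _node(out, (a,), lambda g: (g * (a.data > 0),))


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    pos = a.data > 0
    out = np.where(pos, a.data, slope * a.data)
    return _node(out, (a,), lambda g: (g * np.where(pos, 1.0, slope),))


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out = np.tanh(a.data)
    return _node(out, (a,), lambda g: (g * (1.0 - out * out),))


# ----------------------------------------------------------------------
# reductions
# ----------------------------------------------------------------------

def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, a.data.shape).copy(),)
        gg = g
        if not keepdims:
            gg = np.expand_dims(g, axis)
        return (np.broadcast_to(gg, a.data.shape).copy(),)

    return _node(out, (a,), backward)


def mean_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out = a.data.mean(axis=axis, keepdims=keepdims)
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else axis
        n = int(np.prod([a.data.shape[ax] for ax in axes]))

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g / n, a.data.shape).copy(),)
        gg = g
        if not keepdims:
            gg = np.expand_dims(g, axis)
        return (np.broadcast_to(gg / n, a.data.shape).copy(),)

    return _node(out, (a,), backward)


# ----------------------------------------------------------------------
# spatial primitives (NCHW layout)
# ----------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    n, c, _, _ = xp.shape
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, kh, kw)
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """Zero-padded strided 2-D convolution (cross-correlation) for NCHW."""
    x, w = as_tensor(x), as_tensor(w)
    bt = as_tensor(b) if b is not None else None
    n, c, h, ww_ = x.data.shape
    o, c2, kh, kw = w.data.shape
    if c != c2:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {c2}")
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    if xp.shape[2] < kh or xp.shape[3] < kw:
        raise ValueError("conv2d input smaller than kernel")
    cols, ho, wo = _im2col(xp, kh, kw, stride)
    wmat = w.data.reshape(o, c * kh * kw)
    out = cols @ wmat.T
    out = out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
    if bt is not None:
        out = out + bt.data.reshape(1, o, 1, 1)

    def backward(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1).reshape(-1, o))
        grad_w = (g2.T @ cols).reshape(o, c, kh, kw)
        grad_b = g2.sum(axis=0) if bt is not None else None
        grad_cols = g2 @ wmat
        gc = grad_cols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        gx = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += gc[
                    :, :, :, :, i, j
                ]
        if padding:
            gx = gx[:, :, padding:-padding, padding:-padding]
        if bt is not None:
            return gx, grad_w, grad_b
        return gx, grad_w

    parents = (x, w) if bt is None else (x, w, bt)
    return _node(out, parents, backward)


def avg_pool2d(x, kernel: int, stride: int) -> Tensor:
    """Average pooling with a square kernel, no padding (floor semantics)."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    if h < kernel or w < kernel:
        raise ValueError(
            f"avg_pool2d input {h}x{w} smaller than kernel {kernel}"
        )
    win = np.lib.stride_tricks.sliding_window_view(x.data, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    out = win.mean(axis=(4, 5))
    ho, wo = out.shape[2], out.shape[3]

    def backward(g):
        gx = np.zeros_like(x.data)
        gshare = g / (kernel * kernel)
        for i in range(kernel):
            for j in range(kernel):
                gx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += gshare
        return (gx,)

    return _node(out, (x,), backward)


def upsample_nearest2d(x, scale: int = 2) -> Tensor:
    x = as_tensor(x)
    out = x.data.repeat(scale, axis=2).repeat(scale, axis=3)

    def backward(g):
        n, c, h, w = x.data.shape
        g = g.reshape(n, c, h, scale, w, scale).sum(axis=(3, 5))
        return (g,)

    return _node(out, (x,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _node(out, tuple(tensors), backward)
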