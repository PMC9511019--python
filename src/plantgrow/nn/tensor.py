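"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical substrate for the prediction network: a ``Tensor``
wrapping a float32 ndarray plus the handful of differentiable operations the
model needs (elementwise arithmetic, activations, reductions, reshape/concat,
2-D convolution via im2col, nearest-neighbour upsampling, dropout and a fused
softmax cross-entropy).  Gradients are accumulated by topological traversal of
the recorded graph.  Every op's backward pass is exercised against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "upsample_nearest2x",
    "dropout",
    "softmax",
    "softmax_cross_entropy",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff graph holding a float32 array and its gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
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

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy(), requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node; defaults to d(self)/d(self)=1."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order via iterative DFS
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _needs_graph(self, *others: "Tensor") -> bool:
        return self.requires_grad or any(o.requires_grad for o in others)

    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data**2), other.shape)
                )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = self.data**e

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * e * self.data ** (e - 1.0))

        return self._make(out_data, (self,), backward)

    # ------------------------------------------------------------ elementwise
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / out_data)

        return self._make(out_data, (self,), backward)

    def abs(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g * np.sign(self.data))

        return self._make(np.abs(self.data), (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def leaky_relu(self, negative_slope: float = 0.2):
        slope = np.where(self.data > 0, 1.0, negative_slope).astype(np.float32)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * slope)

        return self._make(self.data * slope, (self,), backward)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).astype(np.float32))

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -------------------------------------------------------------- structural
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return self._make(out_data, (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def clamp01(self) -> "Tensor":
        """Clip to [0,1]; non-differentiable, inference use only."""
        return Tensor(np.clip(self.data, 0.0, 1.0))


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


# --------------------------------------------------------------- convolution
def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, oh: int, ow: int) -> np.ndarray:
    n, c, _, _ = xp.shape
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(n, c * kh * kw, oh * ow)


def _col2im(
    cols: np.ndarray,
    xp_shape: tuple[int, ...],
    kh: int,
    kw: int,
    stride: int,
    oh: int,
    ow: int,
) -> np.ndarray:
    n, c, h, w = xp_shape
    xp = np.zeros(xp_shape, dtype=cols.dtype)
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols[:, :, i, j]
    return xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, square stride/padding."""
    n, cin, h, w = x.shape
    cout, cin_w, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin} vs weight {cin_w}")
    oh = (h + 2 * padding - kh) // stride + 1
    ow = (w + 2 * padding - kw) // stride + 1
    if oh < 1 or ow < 1:
        raise ValueError("conv2d output would be empty")
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data
    cols = _im2col(xp, kh, kw, stride, oh, ow)  # (N, Cin*kh*kw, OH*OW)
    wmat = weight.data.reshape(cout, -1)
    out_data = np.einsum("ok,nkp->nop", wmat, cols, optimize=True)
    out_data = out_data.reshape(n, cout, oh, ow)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gmat = g.reshape(n, cout, oh * ow)
        if bias is not None and bias.requires_grad:
            bias._accumulate(gmat.sum(axis=(0, 2)))
        if weight.requires_grad:
            gw = np.einsum("nop,nkp->ok", gmat, cols, optimize=True)
            weight._accumulate(gw.reshape(weight.shape))
        if x.requires_grad:
            gcols = np.einsum("ok,nop->nkp", wmat, gmat, optimize=True)
            gxp = _col2im(gcols, xp.shape, kh, kw, stride, oh, ow)
            if padding:
                gxp = gxp[:, :, padding : padding + h, padding : padding + w]
            x._accumulate(gxp)

    return Tensor._make(out_data, parents, backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling (NCHW)."""
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        if x.requires_grad:
            n, c, h2, w2 = g.shape
            gg = g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
            x._accumulate(gg)

    return Tensor._make(out_data, (x,), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    keep = (rng.random(x.shape) >= rate).astype(np.float32) / (1.0 - rate)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * keep)

    return Tensor._make(x.data * keep, (x,), backward)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * p).sum(axis=axis, keepdims=True)
            x._accumulate(p * (g - dot))

    return Tensor._make(p, (x,), backward)


def softmax_cross_entropy(logits: Tensor, target: np.ndarray, axis: int = 1) -> Tensor:
    """Mean cross-entropy with softmax over ``axis``.

    ``target`` is either an integer class array (logits shape minus ``axis``)
    or a probability array matching the logits shape (soft targets, as
    produced by temporal mixup of one-hot masks).
    """
    z = logits.data - logits.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)
    logp = z - np.log(e.sum(axis=axis, keepdims=True))
    c = logits.shape[axis]
    if target.shape == logits.shape:
        t = np.asarray(target, dtype=np.float32)
    else:
        ti = np.asarray(target)
        if ti.min() < 0 or ti.max() >= c:
            raise ValueError(
                f"class label {int(ti.max() if ti.max() >= c else ti.min())} outside [0, {c})"
            )
        t = np.moveaxis(np.eye(c, dtype=np.float32)[ti], -1, axis)
    n_items = logits.data.size // c
    loss = -(t * logp).sum() / n_items

    def backward(g):
        if logits.requires_grad:
            logits._accumulate(np.float32(g) * (p - t) / n_items)

    return Tensor._make(np.float32(loss), (logits,), backward)
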