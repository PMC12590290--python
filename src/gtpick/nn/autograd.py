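"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the tape in reverse topological order and
accumulates gradients into ``.grad``. Everything runs in float64 on the CPU,
which keeps finite-difference gradient checks meaningful at ``h ~ 1e-5``.

Only the operations the detector needs are implemented; convolution and
pooling get fused forward/backward rules (im2col / col2im) because composing
them from primitives would dominate the runtime.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "concatenate",
    "stack",
    "softmax",
    "dropout",
    "conv2d",
    "max_pool2d",
    "no_grad",
]

_grad_enabled = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _make(cls, data, parents, backward):
        out = cls(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            grad = np.asarray(grad)
            # keep freshly owned arrays as-is; copy views so later writes to
            # their base cannot alias into the gradient
            self.grad = grad if grad.base is None else grad.copy()
        else:
            self.grad = self.grad + grad

    # -- basic properties ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def __len__(self):
        return len(self.data)

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor._make(self.data + other.data, (self, other), None)

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = backward if out._parents else None
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor._make(self.data * other.data, (self, other), None)

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = backward if out._parents else None
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor._make(self.data ** exponent, (self,), None)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * exponent * self.data ** (exponent - 1.0))

        out._backward = backward if out._parents else None
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor._make(np.matmul(self.data, other.data), (self, other), None)

        def backward():
            if self.requires_grad:
                g = np.matmul(out.grad, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                if other.data.ndim == 2 and self.data.ndim > 2:
                    # collapse batch dims: cheaper than a batched matmul + sum
                    k = self.data.shape[-1]
                    n = out.grad.shape[-1]
                    g = self.data.reshape(-1, k).T @ out.grad.reshape(-1, n)
                else:
                    g = np.matmul(np.swapaxes(self.data, -1, -2), out.grad)
                    g = _unbroadcast(g, other.data.shape)
                other._accum(g)

        out._backward = backward if out._parents else None
        return out

    # -- elementwise functions -----------------------------------------------

    def _unary(self, value: np.ndarray, local_grad: np.ndarray) -> "Tensor":
        out = Tensor._make(value, (self,), None)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * local_grad)

        out._backward = backward if out._parents else None
        return out

    def exp(self):
        v = np.exp(self.data)
        return self._unary(v, v)

    def log(self):
        return self._unary(np.log(self.data), 1.0 / self.data)

    def sqrt(self):
        v = np.sqrt(self.data)
        return self._unary(v, 0.5 / v)

    def sin(self):
        return self._unary(np.sin(self.data), np.cos(self.data))

    def cos(self):
        return self._unary(np.cos(self.data), -np.sin(self.data))

    def tanh(self):
        v = np.tanh(self.data)
        return self._unary(v, 1.0 - v * v)

    def sigmoid(self):
        v = 1.0 / (1.0 + np.exp(-self.data))
        return self._unary(v, v * (1.0 - v))

    def relu(self):
        mask = self.data > 0
        return self._unary(self.data * mask, mask.astype(self.data.dtype))

    def abs(self):
        return self._unary(np.abs(self.data), np.sign(self.data))

    def clamp(self, lo: float, hi: float):
        """Clamp values; gradient passes only through the interior."""
        mask = (self.data >= lo) & (self.data <= hi)
        return self._unary(np.clip(self.data, lo, hi), mask.astype(self.data.dtype))

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward():
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward if out._parents else None
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape manipulation --------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor._make(self.data.reshape(shape), (self,), None)

        def backward():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        out._backward = backward if out._parents else None
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inverse = np.argsort(axes)
        out = Tensor._make(self.data.transpose(axes), (self,), None)

        def backward():
            if self.requires_grad:
                self._accum(out.grad.transpose(inverse))

        out._backward = backward if out._parents else None
        return out

    def __getitem__(self, index):
        out = Tensor._make(self.data[index], (self,), None)

        def backward():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, index, out.grad)
                self._accum(g)

        out._backward = backward if out._parents else None
        return out

    # -- backward pass -------------------------------------------------------

    def backward(self) -> None:
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in visited:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()
                node._backward = None
                node._parents = ()


# -- free functions -----------------------------------------------------------


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, None)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    out._backward = backward if out._parents else None
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor._make(np.stack([t.data for t in tensors], axis=axis), tensors, None)

    def backward():
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(out.grad, i, axis=axis))

    out._backward = backward if out._parents else None
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - x.data.max(axis=axis, keepdims=True)  # constant shift, gradient-safe
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def dropout(x: Tensor, p: float, training: bool, rng: np.random.Generator) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * mask


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2D cross-correlation, NCHW layout, fused im2col forward/backward."""
    n, cin, h, w = x.data.shape
    cout, cin_w, kh, kw = weight.data.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, weight {cin_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (w + 2 * padding - kw) // stride + 1
    # (N, Cin, Ho, Wo, kh, kw) view, then columns (N, Ho*Wo, Cin*kh*kw)
    windows = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, cin * kh * kw)
    wmat = weight.data.reshape(cout, -1)
    out_data = cols @ wmat.T
    if bias is not None:
        out_data = out_data + bias.data
    out_data = out_data.transpose(0, 2, 1).reshape(n, cout, ho, wo)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor._make(out_data, parents, None)

    def backward():
        g = out.grad.reshape(n, cout, ho * wo).transpose(0, 2, 1)  # (N, L, Cout)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 1)))
        if weight.requires_grad:
            dw = np.einsum("nlc,nlk->ck", g, cols)
            weight._accum(dw.reshape(weight.data.shape))
        if x.requires_grad:
            dcols = g @ wmat  # (N, L, Cin*kh*kw)
            dcols = dcols.reshape(n, ho, wo, cin, kh, kw).transpose(0, 3, 4, 5, 1, 2)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += dcols[:, :, i, j]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    out._backward = backward if out._parents else None
    return out


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    n, c, h, w = x.data.shape
    pad_value = -np.inf
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=pad_value)
    ho = (h + 2 * padding - kernel) // stride + 1
    wo = (w + 2 * padding - kernel) // stride + 1
    windows = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    flat = windows.reshape(n, c, ho, wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    out = Tensor._make(out_data, (x,), None)

    def backward():
        if not x.requires_grad:
            return
        dxp = np.zeros_like(xp)
        ki, kj = np.unravel_index(arg, (kernel, kernel))
        nn_, cc, ii, jj = np.meshgrid(np.arange(n), np.arange(c), np.arange(ho),
                                      np.arange(wo), indexing="ij")
        np.add.at(dxp, (nn_, cc, ii * stride + ki, jj * stride + kj), out.grad)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accum(dxp)

    out._backward = backward if out._parents else None
    return out
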