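"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine: each :class:`Tensor` wraps an
``ndarray`` and remembers how to push gradients to its parents.  The op set
is exactly what the networks in this package need (dense algebra, batched
matmul, 1-D convolution, gated-recurrence nonlinearities, softmax, basic
indexing).  Gradients for every op are verified against central finite
differences in the test suite.

All data is float64.  Broadcasting follows NumPy semantics; gradients of
broadcast operands are summed back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "set_dtype", "get_dtype"]

# Global compute dtype. float32 is the training default; gradient-check
# tests switch to float64 for headroom against finite-difference error.
_DTYPE = np.float32


def set_dtype(dtype) -> None:
    global _DTYPE
    _DTYPE = np.dtype(dtype).type


def get_dtype():
    return _DTYPE


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast relative to `shape`."""
    if grad.shape == shape:
        return grad
    # sum extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "_grad_owned")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev
        self._grad_owned = False

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        # First contribution stores a reference (no allocation); a second
        # contribution copies before the in-place add so shared upstream
        # gradient buffers are never mutated.
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    @staticmethod
    def _make(data, parents):
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, _prev=tuple(p for p in parents if p.requires_grad))

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        # iterative topological sort (graphs here can be ~10^3 nodes deep)
        visiting: list[tuple[Tensor, int]] = [(self, 0)]
        seen: set[int] = set()
        order: list[Tensor] = []
        while visiting:
            node, state = visiting.pop()
            if state == 0:
                if id(node) in seen:
                    continue
                seen.add(id(node))
                visiting.append((node, 1))
                for p in node._prev:
                    if id(p) not in seen:
                        visiting.append((p, 0))
            else:
                order.append(node)
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = self._make(self.data + other.data, (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = _bw
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = self._make(self.data * other.data, (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = self._make(self.data / other.data, (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = self._coerce(other)
        out = self._make(self.data @ other.data, (self, other))

        def _bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = _bw
        return out

    def pow(self, exponent: float):
        """Elementwise power with a scalar exponent (exponent 0 -> constant 1)."""
        if exponent == 0:
            return Tensor(np.ones_like(self.data))
        out = self._make(self.data**exponent, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = _bw
        return out

    # ----------------------------------------------------------- nonlinearity
    def exp(self):
        y = np.exp(self.data)
        out = self._make(y, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * y)

        out._backward = _bw
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = _bw
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = self._make(y, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - y * y))

        out._backward = _bw
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = self._make(y, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * y * (1.0 - y))

        out._backward = _bw
        return out

    def relu(self):
        mask = self.data > 0
        out = self._make(self.data * mask, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = _bw
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only where values were in range."""
        mask = (self.data >= lo) & (self.data <= hi)
        out = self._make(np.clip(self.data, lo, hi), (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = _bw
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = self._make(y, (self,))

        def _bw(g):
            if self.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accumulate(y * (g - dot))

        out._backward = _bw
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def _bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        out = self._make(self.data.reshape(*shape), (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = _bw
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = self._make(self.data.transpose(axes), (self,))

        def _bw(g):
            if self.requires_grad:
                inv = np.argsort(axes) if axes else None
                self._accumulate(g.transpose(inv))

        out._backward = _bw
        return out

    def _accumulate_at(self, key, g, fancy: bool) -> None:
        """Add `g` into the slice `key` of this tensor's gradient buffer.

        Avoids materializing a full-size zero array per slice: the buffer is
        allocated once and owned, then written in place.
        """
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
            self._grad_owned = True
        elif not self._grad_owned:
            self.grad = self.grad.copy()
            self._grad_owned = True
        if fancy:
            np.add.at(self.grad, key, g)
        else:
            self.grad[key] += g

    def __getitem__(self, key):
        out = self._make(self.data[key], (self,))
        # basic indexing (ints/slices) selects disjoint elements; fancy
        # indexing may repeat rows and needs add.at
        fancy = any(
            isinstance(k, (np.ndarray, list)) for k in (key if isinstance(key, tuple) else (key,))
        )

        def _bw(g):
            if self.requires_grad:
                self._accumulate_at(key, g, fancy)

        out._backward = _bw
        return out

    def flip(self, axis: int):
        out = self._make(np.flip(self.data, axis=axis), (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(np.flip(g, axis=axis))

        out._backward = _bw
        return out

    def pad1d(self, pad: int):
        """Zero-pad the last axis by `pad` on both sides."""
        if pad == 0:
            return self
        width = [(0, 0)] * (self.data.ndim - 1) + [(pad, pad)]
        out = self._make(np.pad(self.data, width), (self,))

        def _bw(g):
            if self.requires_grad:
                sl = [slice(None)] * (self.data.ndim - 1) + [slice(pad, -pad)]
                self._accumulate(g[tuple(sl)])

        out._backward = _bw
        return out

    def conv1d(self, weight: "Tensor", bias: "Tensor", stride: int, padding: int):
        """1-D convolution over the last axis.

        self: (B, C_in, L); weight: (C_out, C_in, K); bias: (C_out,).
        Returns (B, C_out, L_out) with L_out = floor((L + 2p - K)/s) + 1.
        """
        B, C_in, L = self.data.shape
        C_out, _, K = weight.data.shape
        xp = np.pad(self.data, ((0, 0), (0, 0), (padding, padding)))
        Lp = xp.shape[-1]
        L_out = (Lp - K) // stride + 1
        # (B, C_in, L_out, K) windows -> (B, L_out, C_in*K)
        win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)[:, :, ::stride, :]
        cols = win.transpose(0, 2, 1, 3).reshape(B, L_out, C_in * K)
        w2 = weight.data.reshape(C_out, C_in * K)
        y = cols @ w2.T + bias.data  # (B, L_out, C_out)
        out = self._make(np.ascontiguousarray(y.transpose(0, 2, 1)), (self, weight, bias))

        def _bw(g):
            gy = np.ascontiguousarray(g.transpose(0, 2, 1))  # (B, L_out, C_out)
            if weight.requires_grad:
                gw = gy.reshape(-1, C_out).T @ cols.reshape(-1, C_in * K)
                weight._accumulate(gw.reshape(C_out, C_in, K))
            if bias.requires_grad:
                bias._accumulate(gy.sum(axis=(0, 1)))
            if self.requires_grad:
                gcols = gy @ w2  # (B, L_out, C_in*K)
                gcols = gcols.reshape(B, L_out, C_in, K).transpose(0, 2, 1, 3)
                gxp = np.zeros_like(xp)
                for j in range(K):
                    gxp[:, :, j : j + L_out * stride : stride] += gcols[:, :, :, j]
                gx = gxp[:, :, padding : Lp - padding] if padding else gxp
                self._accumulate(gx)

        out._backward = _bw
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor._make(data, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    out._backward = _bw
    return out


def stack(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor._make(data, tuple(tensors))

    def _bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    out._backward = _bw
    return out
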