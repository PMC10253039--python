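"""Minimal reverse-mode autodiff on NumPy arrays.

The grading networks in this package are small (a few million parameters) and
only ever trained for smoke-scale sanity runs, so they run on a deliberately
compact tape-based tensor core instead of a full deep-learning framework:
every operation records its parents and a backward closure, and
:meth:`Tensor.backward` walks the tape in reverse topological order.

Supported operations are exactly those the detector and grader architectures
need: broadcasted arithmetic, batched matmul, (grouped) 2-D convolution via
im2col, max pooling, nearest-neighbour upsampling, window/axis reshuffling,
the usual activations, and softmax.  Everything is float32.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
        name: str = "",
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = tuple(_parents)
        self._backward = _backward
        self.name = name

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, grad={self.requires_grad}, name={self.name!r})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node through the recorded tape."""
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS: post-order
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            pending = [p for p in node._parents if id(p) not in seen]
            if pending:
                stack.append(node)
                stack.extend(pending)
            else:
                seen.add(id(node))
                topo.append(node)
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _binary(self, other, fwd, bwd_self, bwd_other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(
            fwd(self.data, other.data),
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def backward(grad: np.ndarray) -> None:
            if self.requires_grad or self._parents or self._backward:
                self._accumulate(_unbroadcast(bwd_self(grad, self.data, other.data), self.shape))
            if other.requires_grad or other._parents or other._backward:
                other._accumulate(_unbroadcast(bwd_other(grad, self.data, other.data), other.shape))

        out._backward = backward
        return out

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b, lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b, lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return self._lift(other).__sub__(self)

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b, lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(
            other,
            lambda a, b: a / b,
            lambda g, a, b: g / b,
            lambda g, a, b: -g * a / (b * b),
        )

    def __rtruediv__(self, other):
        return self._lift(other).__truediv__(self)

    def __neg__(self):
        return self * -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data**p, requires_grad=self.requires_grad, _parents=(self,))

        def backward(grad: np.ndarray) -> None:
            self._accumulate(grad * p * self.data ** (p - 1))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.data @ other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def backward(grad: np.ndarray) -> None:
            a, b = self.data, other.data
            ga = grad @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ grad
            self._accumulate(_unbroadcast(ga, a.shape))
            other._accumulate(_unbroadcast(gb, b.shape))

        out._backward = backward
        return out

    # -- elementwise ------------------------------------------------------

    def _unary(self, fwd_val: np.ndarray, grad_fn) -> "Tensor":
        out = Tensor(fwd_val, requires_grad=self.requires_grad, _parents=(self,))

        def backward(grad: np.ndarray) -> None:
            self._accumulate(grad_fn(grad, fwd_val))

        out._backward = backward
        return out

    def exp(self) -> "Tensor":
        return self._unary(np.exp(self.data), lambda g, y: g * y)

    def log(self) -> "Tensor":
        return self._unary(np.log(self.data), lambda g, y: g / self.data)

    def sqrt(self) -> "Tensor":
        return self._unary(np.sqrt(self.data), lambda g, y: g * 0.5 / np.maximum(y, 1e-12))

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        return self._unary(y, lambda g, y_: g * y_ * (1.0 - y_))

    def relu(self) -> "Tensor":
        return self._unary(np.maximum(self.data, 0.0), lambda g, y: g * (self.data > 0))

    def silu(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        y = self.data * s
        return self._unary(y, lambda g, y_: g * (s * (1.0 + self.data * (1.0 - s))))

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_val = self.data.sum(axis=axis, keepdims=keepdims)
        out = Tensor(out_val, requires_grad=self.requires_grad, _parents=(self,))

        def backward(grad: np.ndarray) -> None:
            g = grad
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % self.ndim for a in axes):
                    g = np.expand_dims(g, ax)
            self._accumulate(np.broadcast_to(g, self.shape).astype(np.float32))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a % self.ndim] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self - self.data.max(axis=axis, keepdims=True)  # detached max
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- shape manipulation ----------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), requires_grad=self.requires_grad, _parents=(self,))

        def backward(grad: np.ndarray) -> None:
            self._accumulate(grad.reshape(self.shape))

        out._backward = backward
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), requires_grad=self.requires_grad, _parents=(self,))
        inv = np.argsort(axes)

        def backward(grad: np.ndarray) -> None:
            self._accumulate(grad.transpose(inv))

        out._backward = backward
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], requires_grad=self.requires_grad, _parents=(self,))

        def backward(grad: np.ndarray) -> None:
            g = np.zeros_like(self.data)
            np.add.at(g, key, grad)
            self._accumulate(g)

        out._backward = backward
        return out

    def take(self, index: np.ndarray) -> "Tensor":
        """Gather rows ``self[index]`` (integer fancy indexing on axis 0)."""
        index = np.asarray(index)
        out = Tensor(self.data[index], requires_grad=self.requires_grad, _parents=(self,))

        def backward(grad: np.ndarray) -> None:
            g = np.zeros_like(self.data)
            np.add.at(g, index, grad)
            self._accumulate(g)

        out._backward = backward
        return out

    def roll(self, shifts: tuple[int, ...], axes: tuple[int, ...]) -> "Tensor":
        out = Tensor(np.roll(self.data, shifts, axis=axes), requires_grad=self.requires_grad, _parents=(self,))

        def backward(grad: np.ndarray) -> None:
            self._accumulate(np.roll(grad, tuple(-s for s in shifts), axis=axes))

        out._backward = backward
        return out

    def pad2d(self, pad_h: tuple[int, int], pad_w: tuple[int, int], value: float = 0.0) -> "Tensor":
        """Pad the last two axes of an (..., H, W) tensor."""
        widths = [(0, 0)] * (self.ndim - 2) + [pad_h, pad_w]
        out = Tensor(
            np.pad(self.data, widths, constant_values=value),
            requires_grad=self.requires_grad,
            _parents=(self,),
        )
        h0, h1 = pad_h
        w0, w1 = pad_w

        def backward(grad: np.ndarray) -> None:
            sl = [slice(None)] * (self.ndim - 2) + [
                slice(h0, grad.shape[-2] - h1 or None),
                slice(w0, grad.shape[-1] - w1 or None),
            ]
            self._accumulate(grad[tuple(sl)])

        out._backward = backward
        return out

    # -- spatial operators -----------------------------------------------

    def conv2d(
        self,
        weight: "Tensor",
        bias: "Tensor | None" = None,
        stride: int = 1,
        padding: int = 0,
        groups: int = 1,
    ) -> "Tensor":
        """2-D cross-correlation on an (N, C, H, W) tensor.

        ``groups`` must be 1 (dense) or C (depthwise); those are the only
        variants the architectures here use.
        """
        x, w = self, weight
        n, c, h, wd = x.shape
        if groups == 1:
            c_out, c_in, kh, kw = w.shape
            if c_in != c:
                raise ValueError(f"channel mismatch: input has {c}, weight expects {c_in}")
        elif groups == c:
            c_out, one, kh, kw = w.shape
            if one != 1 or c_out != c:
                raise ValueError("depthwise conv needs weight of shape (C, 1, k, k)")
        else:
            raise ValueError("only dense (groups=1) or depthwise (groups=C) convs are supported")

        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        hp, wp = xp.shape[2], xp.shape[3]
        ho = (hp - kh) // stride + 1
        wo = (wp - kw) // stride + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, kh, kw)

        if groups == 1:
            cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)
            wmat = w.data.reshape(c_out, c * kh * kw)
            out_val = cols @ wmat.T  # (N, Ho*Wo, Cout)
            out_val = out_val.transpose(0, 2, 1).reshape(n, c_out, ho, wo)
        else:
            out_val = np.einsum("nchwij,cij->nchw", win, w.data[:, 0], optimize=True)

        if bias is not None:
            out_val = out_val + bias.data.reshape(1, -1, 1, 1)

        parents = (x, w) if bias is None else (x, w, bias)
        out = Tensor(out_val, requires_grad=any(p.requires_grad for p in parents), _parents=parents)

        def backward(grad: np.ndarray) -> None:
            gout = grad  # (N, Cout, Ho, Wo)
            if bias is not None:
                bias._accumulate(gout.sum(axis=(0, 2, 3)))
            if groups == 1:
                gflat = gout.reshape(n, c_out, ho * wo).transpose(0, 2, 1)  # (N, L, Cout)
                cols_local = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)
                gw = np.einsum("nlo,nlk->ok", gflat, cols_local, optimize=True)
                w._accumulate(gw.reshape(w.shape))
                gcols = gflat @ w.data.reshape(c_out, -1)  # (N, L, C*kh*kw)
                gwin = gcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            else:
                gw = np.einsum("nchw,nchwij->cij", gout, win, optimize=True)
                w._accumulate(gw[:, None].reshape(w.shape))
                gwin = gout[:, :, :, :, None, None] * w.data[:, 0][None, :, None, None, :, :]
            gx = np.zeros((n, c, hp, wp), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    gx[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += gwin[
                        :, :, :, :, i, j
                    ]
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            x._accumulate(gx)

        out._backward = backward
        return out

    def maxpool2d(self, kernel: int, stride: int = 1, padding: int = 0) -> "Tensor":
        n, c, h, w = self.shape
        xp = np.pad(
            self.data,
            ((0, 0), (0, 0), (padding, padding), (padding, padding)),
            constant_values=-np.inf,
        )
        win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]
        flat = win.reshape(*win.shape[:4], kernel * kernel)
        idx = flat.argmax(axis=-1)
        out_val = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        out = Tensor(out_val, requires_grad=self.requires_grad, _parents=(self,))
        ho, wo = out_val.shape[2], out_val.shape[3]

        def backward(grad: np.ndarray) -> None:
            gx = np.zeros_like(xp)
            ki, kj = np.divmod(idx, kernel)
            ni, ci, hi, wi = np.indices(idx.shape)
            np.add.at(gx, (ni, ci, hi * stride + ki, wi * stride + kj), grad)
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            self._accumulate(gx.astype(np.float32))

        out._backward = backward
        return out

    def upsample_nearest2d(self, scale: int = 2) -> "Tensor":
        out_val = self.data.repeat(scale, axis=2).repeat(scale, axis=3)
        out = Tensor(out_val, requires_grad=self.requires_grad, _parents=(self,))
        n, c, h, w = self.shape

        def backward(grad: np.ndarray) -> None:
            g = grad.reshape(n, c, h, scale, w, scale).sum(axis=(3, 5))
            self._accumulate(g)

        out._backward = backward
        return out


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient splitting."""
    ts = list(tensors)
    out = Tensor(
        np.concatenate([t.data for t in ts], axis=axis),
        requires_grad=any(t.requires_grad for t in ts),
        _parents=ts,
    )
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(grad: np.ndarray) -> None:
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * grad.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(grad[tuple(sl)])

    out._backward = backward
    return out


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = list(tensors)
    out = Tensor(
        np.stack([t.data for t in ts], axis=axis),
        requires_grad=any(t.requires_grad for t in ts),
        _parents=ts,
    )

    def backward(grad: np.ndarray) -> None:
        for i, t in enumerate(ts):
            t._accumulate(np.take(grad, i, axis=axis))

    out._backward = backward
    return out
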