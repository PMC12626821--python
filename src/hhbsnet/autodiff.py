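"""Reverse-mode automatic differentiation over numpy arrays.

A small define-by-run engine in the micrograd tradition: every operation
builds a node holding its inputs and a closure that pushes the output
gradient back to them.  It provides exactly the operations the
segmentation network needs — elementwise arithmetic and nonlinearities,
reductions, shape manipulation, 2-D convolution with stride / dilation /
groups, batch normalization, bilinear resizing and a numerically stable
log-softmax.  Everything is float64; all backward rules are checked
against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "batch_norm2d",
    "bilinear_resize",
    "log_softmax",
]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing broadcast axes."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward=None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = tuple(p for p in parents if p.requires_grad)
        self._backward = backward

    # -- bookkeeping ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node through the whole graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
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
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ---------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_sum_to_shape(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_sum_to_shape(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = backward
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_sum_to_shape(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_sum_to_shape(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data / other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_sum_to_shape(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _sum_to_shape(-g * self.data / other.data**2, other.data.shape))

        out._backward = backward
        return out

    def __pow__(self, exponent: float) -> "Tensor":
        e = float(exponent)
        out = Tensor(self.data**e, self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                if e == 0.0:  # constant 1; avoid 0 * inf at zero base
                    self._accumulate(np.zeros_like(self.data))
                else:
                    self._accumulate(g * e * self.data ** (e - 1.0))

        out._backward = backward
        return out

    # -- nonlinearities -----------------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0.0))

        out._backward = backward
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._backward = backward
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * e)

        out._backward = backward
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = backward
        return out

    # -- reductions ----------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))
        in_shape = self.data.shape

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, in_shape).copy())
                return
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                for ax in sorted(a % len(in_shape) for a in axes):
                    g = np.expand_dims(g, ax)
            self._accumulate(np.broadcast_to(g, in_shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def amax(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Maximum along one axis; ties share the gradient equally."""
        m = self.data.max(axis=axis, keepdims=True)
        out_data = m if keepdims else np.squeeze(m, axis=axis)
        out = Tensor(out_data, self.requires_grad, (self,))
        mask = (self.data == m).astype(np.float64)
        mask /= mask.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(mask * g)

        out._backward = backward
        return out

    # -- shape manipulation -------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        in_shape = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(in_shape))

        out._backward = backward
        return out

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        axes = tuple(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        inverse = tuple(np.argsort(axes))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inverse))

        out._backward = backward
        return out

    def broadcast_to(self, shape: Sequence[int]) -> "Tensor":
        shape = tuple(shape)
        out = Tensor(np.broadcast_to(self.data, shape).copy(), self.requires_grad, (self,))
        in_shape = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(_sum_to_shape(g, in_shape))

        out._backward = backward
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accumulate(self.data.swapaxes(-1, -2) @ g)

        out._backward = backward
        return out

    __matmul__ = matmul


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    out._backward = backward
    return out


# ---------------------------------------------------------------------
# 2-D convolution (NCHW) via explicit kernel-tap slicing
# ---------------------------------------------------------------------

def _pad_input(x: np.ndarray, pad: int, mode: str) -> np.ndarray:
    if pad == 0:
        return x
    widths = ((0, 0), (0, 0), (pad, pad), (pad, pad))
    return np.pad(x, widths, mode="wrap" if mode == "wrap" else "constant")


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
    groups: int = 1,
    padding_mode: str = "zeros",
) -> Tensor:
    """2-D convolution (cross-correlation) on [N, C, H, W] input.

    ``weight`` has shape [C_out, C_in/groups, kH, kW].  ``padding_mode``
    is ``"zeros"`` or ``"wrap"`` (circular; used to probe translation
    equivariance on periodic inputs).
    """
    x = as_tensor(x)
    weight = as_tensor(weight)
    N, C, H, W = x.data.shape
    Cout, Cin_g, kH, kW = weight.data.shape
    if C != Cin_g * groups or Cout % groups:
        raise ValueError(
            f"conv2d channel mismatch: input {C}, weight {weight.data.shape}, groups {groups}")
    xp = _pad_input(x.data, padding, padding_mode)
    Hp, Wp = xp.shape[2], xp.shape[3]
    OH = (Hp - ((kH - 1) * dilation + 1)) // stride + 1
    OW = (Wp - ((kW - 1) * dilation + 1)) // stride + 1
    if OH < 1 or OW < 1:
        raise ValueError(f"conv2d output would be empty for input {H}x{W}")

    # cols: [N, groups, Cin_g*kH*kW, OH*OW]
    cols = np.empty((N, C, kH * kW, OH, OW), dtype=np.float64)
    for i in range(kH):
        for j in range(kW):
            hi = i * dilation
            wj = j * dilation
            cols[:, :, i * kW + j] = xp[:, :, hi:hi + OH * stride:stride,
                                        wj:wj + OW * stride:stride]
    cols_g = cols.reshape(N, groups, Cin_g * kH * kW, OH * OW)
    w_g = weight.data.reshape(groups, Cout // groups, Cin_g * kH * kW)
    out_data = np.einsum("gok,ngkp->ngop", w_g, cols_g, optimize=True)
    out_data = out_data.reshape(N, Cout, OH, OW)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, Cout, 1, 1)

    parents = [x, weight] + ([bias] if bias is not None else [])
    out = Tensor(out_data, any(p.requires_grad for p in parents), parents)

    def backward(g):
        g4 = g.reshape(N, groups, Cout // groups, OH * OW)
        if weight.requires_grad:
            dw = np.einsum("ngop,ngkp->gok", g4, cols_g, optimize=True)
            weight._accumulate(dw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.einsum("gok,ngop->ngkp", w_g, g4, optimize=True)
            dcols = dcols.reshape(N, C, kH * kW, OH, OW)
            dxp = np.zeros((N, C, Hp, Wp), dtype=np.float64)
            for i in range(kH):
                for j in range(kW):
                    hi = i * dilation
                    wj = j * dilation
                    dxp[:, :, hi:hi + OH * stride:stride,
                        wj:wj + OW * stride:stride] += dcols[:, :, i * kW + j]
            if padding:
                if padding_mode == "wrap":
                    # each padded position folds back onto its periodic source
                    core = np.zeros((N, C, H, W), dtype=np.float64)
                    rows = (np.arange(Hp) - padding) % H
                    cls = (np.arange(Wp) - padding) % W
                    np.add.at(core, (slice(None), slice(None),
                                     rows[:, None], cls[None, :]), dxp)
                    x._accumulate(core)
                else:
                    x._accumulate(dxp[:, :, padding:-padding, padding:-padding])
            else:
                x._accumulate(dxp)

    out._backward = backward
    return out


# ---------------------------------------------------------------------
# batch normalization over (N, H, W) per channel
# ---------------------------------------------------------------------

def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Channel-wise batch normalization on [N, C, H, W].

    In training mode, normalizes by batch statistics and updates the
    running buffers in place; in inference mode, uses the buffers.
    """
    x = as_tensor(x)
    N, C, H, W = x.data.shape
    gshape = (1, C, 1, 1)
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        n = N * H * W
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        # unbiased variance in the running buffer, biased in the forward
        running_var += momentum * (var * n / max(n - 1, 1))
    else:
        mean = running_mean
        var = running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(gshape)) * inv_std.reshape(gshape)
    out_data = gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape)
    parents = [x, gamma, beta]
    out = Tensor(out_data, any(p.requires_grad for p in parents), parents)

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gw = gamma.data.reshape(gshape) * inv_std.reshape(gshape)
            if training:
                m = N * H * W
                dxhat = g * gamma.data.reshape(gshape)
                t1 = dxhat.sum(axis=(0, 2, 3), keepdims=True) / m
                t2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
                x._accumulate(inv_std.reshape(gshape) * (dxhat - t1 - xhat * t2))
            else:
                x._accumulate(g * gw)

    out._backward = backward
    return out


# ---------------------------------------------------------------------
# bilinear resize with half-pixel-centre sampling
# ---------------------------------------------------------------------

def _resize_axis_weights(n_in: int, n_out: int):
    if n_in == 1:
        return (np.zeros(n_out, int), np.zeros(n_out, int),
                np.ones(n_out), np.zeros(n_out))
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = src - i0
    return i0, i1, 1.0 - w1, w1


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of [N, C, H, W] to [N, C, out_h, out_w]."""
    x = as_tensor(x)
    N, C, H, W = x.data.shape
    r0, r1, rw0, rw1 = _resize_axis_weights(H, out_h)
    c0, c1, cw0, cw1 = _resize_axis_weights(W, out_w)
    rows = (x.data[:, :, r0, :] * rw0[None, None, :, None]
            + x.data[:, :, r1, :] * rw1[None, None, :, None])
    out_data = (rows[:, :, :, c0] * cw0[None, None, None, :]
                + rows[:, :, :, c1] * cw1[None, None, None, :])
    out = Tensor(out_data, x.requires_grad, (x,))

    def backward(g):
        if not x.requires_grad:
            return
        drows = np.zeros((N, C, out_h, W), dtype=np.float64)
        np.add.at(drows, (slice(None), slice(None), slice(None), c0),
                  g * cw0[None, None, None, :])
        np.add.at(drows, (slice(None), slice(None), slice(None), c1),
                  g * cw1[None, None, None, :])
        dx = np.zeros((N, C, H, W), dtype=np.float64)
        np.add.at(dx, (slice(None), slice(None), r0, slice(None)),
                  drows * rw0[None, None, :, None])
        np.add.at(dx, (slice(None), slice(None), r1, slice(None)),
                  drows * rw1[None, None, :, None])
        x._accumulate(dx)

    out._backward = backward
    return out


def log_softmax(x: Tensor, axis: int = 1) -> Tensor:
    """Numerically stable log-softmax along ``axis``."""
    x = as_tensor(x)
    m = x.data.max(axis=axis, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out_data = z - lse
    out = Tensor(out_data, x.requires_grad, (x,))
    softmax = np.exp(out_data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g - softmax * g.sum(axis=axis, keepdims=True))

    out._backward = backward
    return out
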