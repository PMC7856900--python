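"""Minimal reverse-mode automatic differentiation for convolutional nets.

Only the handful of operations a residual dense network needs are
implemented: 2-D convolution (stride 1, "same" padding, odd kernels),
ReLU, channel concatenation, elementwise add, sub-pixel shuffle, mean
absolute error, and scalar combination.  Convolutions run as im2col
matrix products; the input gradient of a stride-1 same-padded
convolution is itself a convolution with the spatially flipped,
channel-transposed kernel, so the backward pass is matmul-only (no
scatter-adds).

Layout is channels-last (NHWC) so the im2col patch matrix is assembled
from contiguous row copies instead of a fully strided transpose.
Convolution weights have shape (k, k, C_in, C_out); all data is float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "relu", "add", "concat", "pixel_shuffle", "mae", "scale", "add_scalars"]


class Tensor:
    """A node in the computation graph: value, gradient, and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.ndim != 0:
            raise ValueError("backward() must start from a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep (one node per conv)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones((), dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad}, name={self.name!r})"


def _make(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = parents
        out._backward = backward
        out.requires_grad = True
    return out


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, k*k*C) patch matrix under same-padding."""
    n, h, w, c = x.shape
    if k == 1:
        return x.reshape(n * h * w, c)
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    col = np.empty((k * k, n, h, w, c), dtype=x.dtype)
    for di in range(k):
        for dj in range(k):
            col[di * k + dj] = xp[:, di : di + h, dj : dj + w, :]
    # (k*k, N, H, W, C) -> (N*H*W, k*k*C) with (di, dj, c) fastest order
    return col.transpose(1, 2, 3, 0, 4).reshape(n * h * w, k * k * c)


def _correlate(x: np.ndarray, weight: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Same-pad stride-1 correlation; returns (output NHWC, patch matrix)."""
    k, _, c, o = weight.shape
    n, h, w, _ = x.shape
    col = _im2col(x, k)
    y = col @ weight.reshape(k * k * c, o)
    return y.reshape(n, h, w, o), col


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """2-D convolution (cross-correlation), stride 1, same padding, odd kernel.

    ``weight`` has shape (k, k, C_in, C_out); ``bias`` shape (C_out,).
    """
    k, k2, c, o = weight.data.shape
    if k != k2 or k % 2 == 0:
        raise ValueError("kernel must be square with odd size")
    if x.data.shape[-1] != c:
        raise ValueError(f"channel mismatch: input has {x.data.shape[-1]}, kernel expects {c}")
    n, h, w, _ = x.data.shape
    y, col = _correlate(x.data, weight.data)
    if bias is not None:
        y += bias.data

    def backward(gy: np.ndarray) -> None:
        gy_mat = gy.reshape(n * h * w, o)
        if weight.requires_grad or weight._parents:
            gw = col.T @ gy_mat
            weight._accumulate(gw.reshape(k, k, c, o))
        if bias is not None and (bias.requires_grad or bias._parents):
            bias._accumulate(gy_mat.sum(axis=0))
        if x.requires_grad or x._parents:
            # grad wrt input = same-pad correlation with flipped, transposed kernel
            w_t = weight.data[::-1, ::-1].transpose(0, 1, 3, 2)
            gx, _ = _correlate(gy, np.ascontiguousarray(w_t))
            x._accumulate(gx)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(y, parents, backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, np.float32(0.0))

    def backward(gy: np.ndarray) -> None:
        if x.requires_grad or x._parents:
            x._accumulate(gy * mask)

    return _make(out_data, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError("add requires equal shapes")

    def backward(gy: np.ndarray) -> None:
        if a.requires_grad or a._parents:
            a._accumulate(gy)
        if b.requires_grad or b._parents:
            b._accumulate(gy)

    return _make(a.data + b.data, (a, b), backward)


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the channel (last) axis."""
    sizes = [t.data.shape[-1] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(gy: np.ndarray) -> None:
        for t, g in zip(tensors, np.split(gy, splits, axis=-1)):
            if t.requires_grad or t._parents:
                t._accumulate(g)

    return _make(np.concatenate([t.data for t in tensors], axis=-1), tuple(tensors), backward)


def pixel_shuffle(x: Tensor, r: int) -> Tensor:
    """Rearrange (N, H, W, C*r^2) -> (N, H*r, W*r, C) (sub-pixel upsampling)."""
    n, h, w, crr = x.data.shape
    if crr % (r * r) != 0:
        raise ValueError("channel count not divisible by scale^2")
    c = crr // (r * r)
    y = (
        x.data.reshape(n, h, w, r, r, c)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(n, h * r, w * r, c)
    )

    def backward(gy: np.ndarray) -> None:
        if x.requires_grad or x._parents:
            g = (
                gy.reshape(n, h, r, w, r, c)
                .transpose(0, 1, 3, 2, 4, 5)
                .reshape(n, h, w, crr)
            )
            x._accumulate(g)

    return _make(y, (x,), backward)


def mae(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean absolute error against a constant target."""
    target = np.asarray(target, dtype=np.float32)
    diff = pred.data - target
    out_data = np.abs(diff).mean(dtype=np.float32)

    def backward(gy: np.ndarray) -> None:
        if pred.requires_grad or pred._parents:
            pred._accumulate(gy * np.sign(diff) / np.float32(diff.size))

    return _make(np.asarray(out_data, dtype=np.float32), (pred,), backward)


def scale(x: Tensor, s: float) -> Tensor:
    s = np.float32(s)

    def backward(gy: np.ndarray) -> None:
        if x.requires_grad or x._parents:
            x._accumulate(gy * s)

    return _make(x.data * s, (x,), backward)


def add_scalars(terms: list[Tensor]) -> Tensor:
    def backward(gy: np.ndarray) -> None:
        for t in terms:
            if t.requires_grad or t._parents:
                t._accumulate(gy)

    return _make(np.sum([t.data for t in terms]).astype(np.float32), tuple(terms), backward)
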