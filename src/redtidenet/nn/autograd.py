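"""Minimal reverse-mode autodiff on NumPy arrays.

The engine implements exactly the operations the segmentation models need:
dilated 2-D convolution, 2x2 transposed convolution, 2x2 max pooling, batch
normalization, channel-wise 1-D convolution (for channel attention), dropout,
elementwise arithmetic with broadcasting, concatenation, and a fused masked
softmax cross-entropy loss. Everything is float32; convolutions lower to
im2col + BLAS matmul.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = [
    "Tensor",
    "Parameter",
    "add",
    "mul",
    "relu",
    "sigmoid",
    "reshape",
    "concat",
    "conv2d",
    "depthwise_conv2d",
    "conv_transpose2x2",
    "maxpool2x2",
    "global_avg_pool",
    "expand_hw",
    "conv1d_channels",
    "dropout",
    "batchnorm2d",
    "masked_softmax_cross_entropy",
]


def _f32(x) -> np.ndarray:
    a = np.asarray(x)
    return a.astype(np.float32) if a.dtype != np.float32 else a


class Tensor:
    """Node in the computation graph wrapping a float32 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(
        self,
        data,
        parents: Sequence["Tensor"] = (),
        backward_fn: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None,
        requires_grad: bool = False,
    ):
        self.data = _f32(data)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward_fn = backward_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-accumulate gradients from this node to all parameters."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep U-Net graphs overflow recursion
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): _f32(grad)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward_fn(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] += pg
                else:
                    grads[id(p)] = pg

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A leaf tensor that accumulates gradients."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)

    def zero_grad(self) -> None:
        self.grad = None


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data
    return Tensor(out, (a, b), lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)))


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data
    return Tensor(
        out,
        (a, b),
        lambda g: (_unbroadcast(g * b.data, a.data.shape), _unbroadcast(g * a.data, b.data.shape)),
    )


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, (x,), lambda g: (g * mask,))


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor(s, (x,), lambda g: (g * s * (1.0 - s),))


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    old = x.data.shape
    return Tensor(x.data.reshape(shape), (x,), lambda g: (g.reshape(old),))


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: np.ndarray):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(data, tuple(tensors), backward)


def _im2col(xp: np.ndarray, k: int, dilation: int, H: int, W: int) -> np.ndarray:
    """(N, C, Hp, Wp) padded input -> (N, C*k*k, H*W) patch matrix."""
    N, C = xp.shape[:2]
    s0, s1, s2, s3 = xp.strides
    view = as_strided(
        xp,
        shape=(N, C, k, k, H, W),
        strides=(s0, s1, s2 * dilation, s3 * dilation, s2, s3),
    )
    return np.ascontiguousarray(view).reshape(N, C * k * k, H * W)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """'Same' 2-D convolution, stride 1, odd kernel, padding = dilation*(k-1)//2.

    x: (N, C_in, H, W); w: (C_out, C_in, k, k); b: (C_out,).
    """
    N, Cin, H, W = x.data.shape
    Cout, Cin_w, k, _ = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input has {Cin}, kernel expects {Cin_w}")
    if k % 2 == 0:
        raise ValueError("conv2d requires an odd kernel size")
    pad = dilation * (k - 1) // 2
    if pad:
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    else:
        xp = x.data
    cols = _im2col(xp, k, dilation, H, W)  # (N, Cin*k*k, H*W)
    w2 = w.data.reshape(Cout, -1)
    out = np.matmul(w2, cols).reshape(N, Cout, H, W)
    if b is not None:
        out += b.data.reshape(1, Cout, 1, 1)

    def backward(g: np.ndarray):
        g2 = g.reshape(N, Cout, H * W)
        # batched gemm + sum beats tensordot here (avoids large transposes)
        dw = np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0).reshape(w.data.shape)
        dcols = np.matmul(w2.T, g2).reshape(N, Cin, k, k, H, W)
        dxp = np.zeros_like(xp)
        for ky in range(k):
            for kx in range(k):
                dxp[:, :, ky * dilation : ky * dilation + H, kx * dilation : kx * dilation + W] += dcols[
                    :, :, ky, kx
                ]
        dx = dxp[:, :, pad : pad + H, pad : pad + W] if pad else dxp
        db = g2.sum(axis=(0, 2)) if b is not None else None
        return (dx, dw, db) if b is not None else (dx, dw)

    parents = (x, w, b) if b is not None else (x, w)
    return Tensor(out, parents, backward)


def depthwise_conv2d(x: Tensor, w: Tensor, dilation: int = 1) -> Tensor:
    """Per-channel 'same' 3x3 (or kxk) convolution. w: (C, k, k)."""
    N, C, H, W = x.data.shape
    Cw, k, _ = w.data.shape
    if C != Cw:
        raise ValueError("depthwise kernel channel mismatch")
    pad = dilation * (k - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s0, s1, s2, s3 = xp.strides
    view = as_strided(
        xp, shape=(N, C, k, k, H, W), strides=(s0, s1, s2 * dilation, s3 * dilation, s2, s3)
    )
    patches = np.ascontiguousarray(view)
    out = np.einsum("ncklhw,ckl->nchw", patches, w.data, optimize=True)

    def backward(g: np.ndarray):
        dw = np.einsum("ncklhw,nchw->ckl", patches, g, optimize=True)
        dxp = np.zeros_like(xp)
        for ky in range(k):
            for kx in range(k):
                dxp[:, :, ky * dilation : ky * dilation + H, kx * dilation : kx * dilation + W] += (
                    g * w.data[:, ky, kx].reshape(1, C, 1, 1)
                )
        dx = dxp[:, :, pad : pad + H, pad : pad + W] if pad else dxp
        return dx, dw

    return Tensor(out, (x, w), backward)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution, kernel 2, stride 2 (exact spatial doubling).

    x: (N, C_in, H, W); w: (C_in, C_out, 2, 2). With stride == kernel the
    output windows do not overlap, so the op is a per-pixel linear map.
    """
    N, Cin, H, W = x.data.shape
    Cin_w, Cout = w.data.shape[:2]
    if Cin != Cin_w:
        raise ValueError("channel mismatch in transposed convolution")
    # (N, H, W, Cin) @ (Cin, Cout*4) -> (N, H, W, Cout, 2, 2)
    w2 = w.data.reshape(Cin, Cout * 4)
    out6 = np.matmul(x.data.transpose(0, 2, 3, 1).reshape(N * H * W, Cin), w2)
    out6 = out6.reshape(N, H, W, Cout, 2, 2)
    out = out6.transpose(0, 3, 1, 4, 2, 5).reshape(N, Cout, 2 * H, 2 * W)
    if b is not None:
        out += b.data.reshape(1, Cout, 1, 1)

    def backward(g: np.ndarray):
        g6 = g.reshape(N, Cout, H, 2, W, 2).transpose(0, 2, 4, 1, 3, 5).reshape(N * H * W, Cout * 4)
        xin = x.data.transpose(0, 2, 3, 1).reshape(N * H * W, Cin)
        dw = (xin.T @ g6).reshape(w.data.shape)
        dx = (g6 @ w2.T).reshape(N, H, W, Cin).transpose(0, 3, 1, 2)
        db = g.sum(axis=(0, 2, 3)) if b is not None else None
        return (dx, dw, db) if b is not None else (dx, dw)

    parents = (x, w, b) if b is not None else (x, w)
    return Tensor(out, parents, backward)


def maxpool2x2(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2x2 needs even spatial dimensions")
    Ho, Wo = H // 2, W // 2
    xr = x.data.reshape(N, C, Ho, 2, Wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, Ho, Wo, 4)
    idx = xr.argmax(axis=4)  # first max wins ties: deterministic
    out = np.take_along_axis(xr, idx[..., None], axis=4)[..., 0]

    def backward(g: np.ndarray):
        dxr = np.zeros((N, C, Ho, Wo, 4), dtype=np.float32)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=4)
        return (dxr.reshape(N, C, Ho, Wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W),)

    return Tensor(out, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean (the channel descriptor)."""
    N, C, H, W = x.data.shape
    out = x.data.mean(axis=(2, 3))

    def backward(g: np.ndarray):
        return (np.broadcast_to(g[:, :, None, None] / (H * W), x.data.shape).astype(np.float32).copy(),)

    return Tensor(out, (x,), backward)


def expand_hw(x: Tensor, H: int, W: int) -> Tensor:
    """(N, C) -> (N, C, H, W) constant spatial broadcast."""
    out = np.broadcast_to(x.data[:, :, None, None], x.data.shape + (H, W)).astype(np.float32).copy()
    return Tensor(out, (x,), lambda g: (g.sum(axis=(2, 3)),))


def conv1d_channels(s: Tensor, w: Tensor) -> Tensor:
    """Weight-shared 1-D convolution across the channel axis, 'same' zero pad.

    s: (N, C) channel descriptors; w: (k,) with k odd.
    """
    N, C = s.data.shape
    (k,) = w.data.shape
    if k % 2 == 0:
        raise ValueError("channel 1-D convolution requires an odd kernel size")
    pad = (k - 1) // 2
    sp = np.pad(s.data, ((0, 0), (pad, pad)))
    st0, st1 = sp.strides
    view = as_strided(sp, shape=(N, C, k), strides=(st0, st1, st1))
    patches = np.ascontiguousarray(view)
    out = patches @ w.data

    def backward(g: np.ndarray):
        dw = np.einsum("nck,nc->k", patches, g, optimize=True)
        dsp = np.zeros_like(sp)
        for j in range(k):
            dsp[:, j : j + C] += g * w.data[j]
        return dsp[:, pad : pad + C], dw

    return Tensor(out, (s, w), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, train: bool) -> Tensor:
    if not train or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(np.float32) / (1.0 - p)
    return Tensor(x.data * keep, (x,), lambda g: (g * keep,))


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    train: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization; running stats mutated in train mode."""
    N, C, H, W = x.data.shape
    if train:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, C, 1, 1)) * invstd.reshape(1, C, 1, 1)
    out = xhat * gamma.data.reshape(1, C, 1, 1) + beta.data.reshape(1, C, 1, 1)

    def backward(g: np.ndarray):
        dgamma = (g * xhat).sum(axis=(0, 2, 3))
        dbeta = g.sum(axis=(0, 2, 3))
        dxhat = g * gamma.data.reshape(1, C, 1, 1)
        if train:
            m = N * H * W
            sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
            sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            dx = (invstd.reshape(1, C, 1, 1) / m) * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)
        else:
            dx = dxhat * invstd.reshape(1, C, 1, 1)
        return dx.astype(np.float32), dgamma, dbeta

    return Tensor(out, (x, gamma, beta), backward)


def masked_softmax_cross_entropy(
    logits: Tensor, labels: np.ndarray, valid: np.ndarray
) -> Tensor:
    """Mean cross-entropy of softmax(logits) over valid pixels only.

    logits: (N, K, H, W); labels: (N, H, W) int in [0, K); valid: (N, H, W) bool.
    Fused op: the softmax and the loss share one backward pass.
    """
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("masked loss requires at least one valid pixel")
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    N, K, H, W = p.shape
    onehot_idx = labels.astype(np.int64)
    picked = np.take_along_axis(p, onehot_idx[:, None, :, :], axis=1)[:, 0]
    logp = np.log(np.clip(picked, 1e-12, None))
    loss = -(logp * valid).sum() / n_valid

    def backward(g: np.ndarray):
        grad = p.copy()
        np.put_along_axis(grad, onehot_idx[:, None, :, :], (picked - 1.0)[:, None], axis=1)
        grad *= valid[:, None, :, :] / n_valid
        return (grad.astype(np.float32) * g,)

    return Tensor(loss, (logits,), backward)
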